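import numpy as np
import pandas as pd
import pytest
from helpers import all_pairs_links_oracle

from epiprime import linkage


def peaks(rows, **extra):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for k, v in extra.items():
        df[k] = v
    return df


def genes_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "tss", "gene_id"])
    df["strand"] = "+"
    df["body_start"] = df["tss"]
    df["body_end"] = df["tss"] + 1000
    return df


class TestLinking:
    def test_boundary_4999_in_5001_out(self):
        pk = peaks([("chr1", 100_000, 100_500)])
        gn = genes_df([("chr1", 100_000 - 4_999, "near"),
                       ("chr1", 100_000 - 5_001, "far")])
        links = linkage.link_peaks_to_genes(pk, gn, window=5_000)
        assert list(links["gene_id"]) == ["near"]
        assert links["distance"].iloc[0] == 4_999

    def test_tss_inside_peak_distance_zero(self):
        links = linkage.link_peaks_to_genes(
            peaks([("chr1", 100, 600)]), genes_df([("chr1", 300, "g")]))
        assert links["distance"].iloc[0] == 0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            pk = peaks([("chr1" if rng.random() < 0.7 else "chr2",
                         int(s), int(s) + int(rng.integers(100, 1000)))
                        for s in rng.integers(0, 200_000, size=50)])
            gn = genes_df([("chr1" if rng.random() < 0.7 else "chr2",
                            int(t), f"g{j}")
                           for j, t in enumerate(rng.integers(0, 200_000,
                                                              size=40))])
            got = linkage.link_peaks_to_genes(pk, gn, window=5_000)
            expected = all_pairs_links_oracle(pk, gn, 5_000)
            assert sorted(zip(got["peak_index"], got["gene_id"],
                              got["distance"])) == expected

    def test_enlarging_window_never_drops_links(self):
        rng = np.random.default_rng(7)
        pk = peaks([("chr1", int(s), int(s) + 500)
                    for s in rng.integers(0, 100_000, size=30)])
        gn = genes_df([("chr1", int(t), f"g{j}")
                       for j, t in enumerate(rng.integers(0, 100_000, size=30))])
        prev = set()
        for window in (1_000, 5_000, 20_000):
            links = linkage.link_peaks_to_genes(pk, gn, window=window)
            keys = set(zip(links["peak_index"], links["gene_id"]))
            assert prev <= keys
            prev = keys


class TestFoldChangeFilter:
    def make_links(self, label, sa, sb):
        return pd.DataFrame({"peak_index": [0], "gene_id": ["g"],
                             "distance": [0], "label": [label],
                             "signal_a": [sa], "signal_b": [sb]})

    def test_cluster_n_strong_ratio_kept(self):
        out = linkage.fold_change_filter(self.make_links("N", 1.0, 10.0))
        assert len(out) == 1  # (10+1)/(1+1) = 5.5 > 2

    def test_cluster_c_exempt(self):
        out = linkage.fold_change_filter(self.make_links("C", 5.0, 5.0))
        assert len(out) == 1

    def test_cluster_i_weak_ratio_dropped(self):
        out = linkage.fold_change_filter(self.make_links("I", 3.0, 2.0))
        assert out.empty  # (3+1)/(2+1) = 4/3 < 2

    def test_never_removes_cluster_c(self):
        rng = np.random.default_rng(3)
        links = pd.DataFrame({
            "peak_index": range(50), "gene_id": [f"g{i}" for i in range(50)],
            "distance": 0,
            "label": rng.choice(["C", "I", "N"], size=50),
            "signal_a": rng.uniform(0, 10, 50),
            "signal_b": rng.uniform(0, 10, 50)})
        out = linkage.fold_change_filter(links)
        assert (out["label"] == "C").sum() == (links["label"] == "C").sum()


class TestInductionGenes:
    def expr(self, data):
        df = pd.DataFrame(data, index=["a1", "a2", "b1", "b2"]).T
        df.index.name = "gene_id"
        return df

    def test_strong_induction_detected(self):
        expr = self.expr({"g1": [0, 0, 10, 10]})
        links = pd.DataFrame({"gene_id": ["g1"], "label": ["C"],
                              "peak_index": [0], "distance": [0]})
        induced, missing = linkage.induction_genes(
            links, expr, ["a1", "a2"], ["b1", "b2"])
        assert induced == ["g1"] and missing == []

    def test_flat_gene_excluded(self):
        expr = self.expr({"g1": [10, 10, 10, 10]})
        links = pd.DataFrame({"gene_id": ["g1"], "label": ["C"],
                              "peak_index": [0], "distance": [0]})
        induced, _ = linkage.induction_genes(links, expr, ["a1", "a2"],
                                             ["b1", "b2"])
        assert induced == []

    def test_missing_gene_recorded_and_skipped(self):
        expr = self.expr({"g1": [0, 0, 10, 10]})
        links = pd.DataFrame({"gene_id": ["g1", "ghost"], "label": ["C", "C"],
                              "peak_index": [0, 1], "distance": [0, 0]})
        induced, missing = linkage.induction_genes(
            links, expr, ["a1", "a2"], ["b1", "b2"])
        assert induced == ["g1"] and missing == ["ghost"]

    def test_recovers_planted_induced_genes(self, default_dataset, default_run):
        """F1 >= 0.9 against the planted induced genes (whose promoters sit
        in commonly open chromatin) on the default synthetic study."""
        from epiprime import io
        outdir, _ = default_run
        induced = set(io.read_table(outdir / "induction_genes.tsv")["gene_id"])
        truth = set(default_dataset.truth.genes.loc[
            default_dataset.truth.genes["cls"] == "induced", "gene_id"])
        tp = len(induced & truth)
        precision = tp / max(len(induced), 1)
        recall = tp / max(len(truth), 1)
        f1 = 2 * precision * recall / max(precision + recall, 1e-9)
        assert f1 >= 0.9


class TestPrimedPeaks:
    def calls(self, labels):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [i * 10_000 for i in range(len(labels))],
            "end": [i * 10_000 + 500 for i in range(len(labels))],
            "label": labels})

    def test_c_peak_with_induced_nearest_gene_returned(self):
        calls = self.calls(["C"])
        links = pd.DataFrame({"peak_index": [0], "gene_id": ["g1"],
                              "distance": [100], "label": ["C"]})
        out = linkage.primed_promoter_peaks(calls, {"g1"}, links)
        assert len(out) == 1

    def test_n_peak_excluded_even_if_induced(self):
        calls = self.calls(["N"])
        links = pd.DataFrame({"peak_index": [0], "gene_id": ["g1"],
                              "distance": [100], "label": ["N"]})
        out = linkage.primed_promoter_peaks(calls, {"g1"}, links)
        assert out.empty

    def test_nearest_tie_consults_both_genes(self):
        calls = self.calls(["C"])
        links = pd.DataFrame({"peak_index": [0, 0],
                              "gene_id": ["flat_gene", "induced_gene"],
                              "distance": [200, 200], "label": ["C", "C"]})
        out = linkage.primed_promoter_peaks(calls, {"induced_gene"}, links)
        assert len(out) == 1

    def test_nearer_flat_gene_blocks_priming(self):
        calls = self.calls(["C"])
        links = pd.DataFrame({"peak_index": [0, 0],
                              "gene_id": ["flat_gene", "induced_gene"],
                              "distance": [100, 200], "label": ["C", "C"]})
        out = linkage.primed_promoter_peaks(calls, {"induced_gene"}, links)
        assert out.empty

    def test_primed_subset_of_cluster_c(self, default_run):
        from epiprime import io
        outdir, _ = default_run
        primed = io.read_table(outdir / "primed_peaks.tsv")
        calls = io.read_table(outdir / "openness.tsv")
        ckeys = set(zip(calls.loc[calls["label"] == "C", "chrom"],
                        calls.loc[calls["label"] == "C", "start"]))
        assert set(zip(primed["chrom"], primed["start"])) <= ckeys


class TestTssFraction:
    def test_all_peaks_on_tss(self):
        pk = peaks([("chr1", 1000, 1500), ("chr1", 9000, 9500)])
        gn = genes_df([("chr1", 1250, "g1"), ("chr1", 9250, "g2")])
        assert linkage.tss_fraction(pk, gn) == 1.0

    def test_no_gene_in_window(self):
        pk = peaks([("chr1", 1000, 1500)])
        gn = genes_df([("chr1", 500_000, "g1")])
        assert linkage.tss_fraction(pk, gn) == 0.0

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            linkage.tss_fraction(peaks([]), genes_df([("chr1", 0, "g")]))

    def test_matches_brute_force_and_window_monotonic(self):
        rng = np.random.default_rng(11)
        pk = peaks([("chr1", int(s), int(s) + 300)
                    for s in rng.integers(0, 100_000, size=40)])
        gn = genes_df([("chr1", int(t), f"g{j}")
                       for j, t in enumerate(rng.integers(0, 100_000, size=25))])
        prev = 0.0
        for window in (500, 2_000, 5_000, 20_000):
            frac = linkage.tss_fraction(pk, gn, window=window)
            brute = np.mean([
                any(g["chrom"] == p["chrom"]
                    and min(abs(g["tss"] - p["start"]),
                            abs(g["tss"] - (p["end"] - 1))) <= window
                    or (g["chrom"] == p["chrom"]
                        and p["start"] <= g["tss"] < p["end"])
                    for _, g in gn.iterrows())
                for _, p in pk.iterrows()])
            assert frac == pytest.approx(brute)
            assert frac >= prev
            prev = frac
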