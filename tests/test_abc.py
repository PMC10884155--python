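import numpy as np
import pandas as pd
import pytest

from epiprime import abc, io


def elements_df(rows):
    """rows: (chrom, start, end, activity)"""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "activity"])
    df["is_promoter"] = False
    df["owner_gene"] = ""
    return df


GENE = {"gene_id": "g1", "chrom": "chr1", "tss": 1_000_000}
MODEL = abc.ContactModel()


class TestActivity:
    def test_geometric_mean(self):
        assert abc.element_activity(4, 9) == 6.0

    def test_zero_count_zeroes_activity(self):
        assert abc.element_activity(0, 100) == 0.0

    def test_matches_sqrt_product(self, rng):
        a = rng.integers(0, 500, 100)
        k = rng.integers(0, 500, 100)
        assert np.allclose(abc.element_activity(a, k), np.sqrt(a * k))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            abc.element_activity(-1, 5)


class TestContact:
    def test_powerlaw_closed_form(self):
        model = abc.ContactModel(gamma=1.0, d0=5_000)
        assert model.contact(0) / model.contact(5_000) == pytest.approx(2.0)

    def test_equidistant_symmetry(self):
        assert MODEL.contact(12_345) == MODEL.contact(12_345)
        d = np.array([1_000, 1_000])
        c = MODEL.contact(d)
        assert c[0] == c[1]

    def test_non_increasing_in_distance(self):
        d = np.linspace(0, 1e6, 100)
        c = MODEL.contact(d)
        assert (np.diff(c) <= 0).all()

    def test_constant_table_is_distance_independent(self):
        table = pd.DataFrame({"bin_start": [0, 10_000, 20_000],
                              "contact": [3.0, 3.0, 3.0]})
        model = abc.ContactModel(mode="table", table=table)
        assert model.contact(500) == model.contact(25_000) == 3.0

    def test_table_bin_lookup(self):
        table = pd.DataFrame({"bin_start": [0, 10_000, 20_000],
                              "contact": [4.0, 2.0, 1.0]})
        model = abc.ContactModel(mode="table", table=table)
        assert list(model.contact([0, 9_999, 10_000, 29_999])) == [4, 4, 2, 1]

    def test_beyond_table_range_rejected(self):
        table = pd.DataFrame({"bin_start": [0, 10_000], "contact": [2.0, 1.0]})
        model = abc.ContactModel(mode="table", table=table)
        with pytest.raises(ValueError):
            model.contact(20_000)

    def test_increasing_table_rejected(self):
        table = pd.DataFrame({"bin_start": [0, 10_000], "contact": [1.0, 2.0]})
        with pytest.raises(ValueError):
            abc.ContactModel(mode="table", table=table)


class TestScores:
    def test_single_element_scores_one(self):
        elems = elements_df([("chr1", 999_000, 999_250, 7.0)])
        out = abc.abc_scores(elems, GENE, MODEL)
        assert len(out) == 1
        assert out["score"].iloc[0] == 1.0

    def test_equal_activity_equidistant_half_each(self):
        elems = elements_df([("chr1", 990_000, 990_250, 5.0),
                             ("chr1", 1_009_750, 1_010_000, 5.0)])
        out = abc.abc_scores(elems, GENE, MODEL)
        assert list(out["score"]) == pytest.approx([0.5, 0.5])

    def test_worked_example_10_5_5(self):
        # equidistant elements with activities 10, 5, 5 -> 0.5, 0.25, 0.25;
        # all pass the 0.02 threshold
        elems = elements_df([("chr1", 990_000, 990_250, 10.0),
                             ("chr1", 1_009_750, 1_010_000, 5.0),
                             ("chr1", 990_000, 990_250, 5.0)])
        out = abc.abc_scores(elems, GENE, MODEL, threshold=0.02)
        assert sorted(out["score"], reverse=True) == pytest.approx(
            [0.5, 0.25, 0.25])

    def test_scores_sum_to_one_before_threshold(self, rng):
        rows = [("chr1", int(s), int(s) + 250, float(rng.uniform(0.1, 50)))
                for s in rng.integers(500_000, 1_500_000, size=40)]
        out = abc.abc_scores(elements_df(rows), GENE, MODEL, threshold=0.0)
        assert out["score"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, rng):
        rows = [("chr1", int(s), int(s) + 250, float(rng.uniform(0.1, 50)))
                for s in rng.integers(500_000, 1_500_000, size=20)]
        base = abc.abc_scores(elements_df(rows), GENE, MODEL, threshold=0.0)
        scaled_rows = [(c, s, e, a * 37.5) for c, s, e, a in rows]
        scaled = abc.abc_scores(elements_df(scaled_rows), GENE, MODEL,
                                threshold=0.0)
        assert np.allclose(base["score"], scaled["score"])

    def test_increasing_one_activity_raises_its_score_lowers_others(self):
        rows = [("chr1", 990_000, 990_250, 5.0),
                ("chr1", 1_020_000, 1_020_250, 5.0),
                ("chr1", 1_050_000, 1_050_250, 5.0)]
        before = abc.abc_scores(elements_df(rows), GENE, MODEL, threshold=0.0)
        rows[0] = ("chr1", 990_000, 990_250, 10.0)
        after = abc.abc_scores(elements_df(rows), GENE, MODEL, threshold=0.0)
        assert after["score"].iloc[0] > before["score"].iloc[0]
        assert (after["score"].iloc[1:].to_numpy()
                <= before["score"].iloc[1:].to_numpy()).all()

    def test_promoter_participates_in_denominator_but_not_output(self):
        elems = elements_df([("chr1", 990_000, 990_250, 5.0)])
        prom = elements_df([("chr1", 999_750, 1_000_250, 5.0)])
        prom["is_promoter"] = True
        prom["owner_gene"] = "g1"
        out = abc.abc_scores(pd.concat([elems, prom], ignore_index=True),
                             GENE, MODEL, threshold=0.0)
        assert list(out["gene_id"]) == ["g1"]
        assert len(out) == 1
        assert out["score"].iloc[0] < 1.0  # promoter absorbed part of the mass

    def test_all_zero_activity_yields_no_pairs(self):
        elems = elements_df([("chr1", 990_000, 990_250, 0.0)])
        out = abc.abc_scores(elems, GENE, MODEL)
        assert out.empty


class TestCandidateElements:
    def frags(self, mids):
        mids = np.asarray(mids)
        return pd.DataFrame({"chrom": "chr1", "start": mids - 50,
                             "end": mids + 50})

    def peaks(self, summits):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": [s - 300 for s in summits],
            "end": [s + 300 for s in summits],
            "summit": summits,
            "score": 1.0})

    def test_top_n_selection_matches_sort_oracle(self, rng):
        summits = [5_000 + 2_000 * i for i in range(10)]
        counts = rng.integers(1, 100, size=10)
        mids = np.concatenate([
            np.full(c, s) for s, c in zip(summits, counts)])
        elems = abc.make_candidate_elements(self.peaks(summits),
                                            self.frags(mids), top_n=3)
        top3 = sorted(counts, reverse=True)[:3]
        assert sorted(elems["atac_count"], reverse=True) == top3

    def test_blacklisted_element_removed(self):
        summits = [5_000, 50_000]
        blacklist = pd.DataFrame({"chrom": ["chr1"], "start": [4_000],
                                  "end": [6_000]})
        elems = abc.make_candidate_elements(
            self.peaks(summits), self.frags([5_000, 50_000]),
            blacklist=blacklist)
        assert list(elems["start"]) == [50_000 - 125]

    def test_overlapping_elements_merged_with_recount(self):
        summits = [5_000, 5_100]  # 250bp elements overlap by 150
        elems = abc.make_candidate_elements(
            self.peaks(summits), self.frags([5_000, 5_050, 5_100]))
        assert len(elems) == 1
        assert (elems["start"].iloc[0], elems["end"].iloc[0]) == (4_875, 5_225)
        assert elems["atac_count"].iloc[0] == 3  # recounted, not summed


class TestBedpe:
    def test_empty_pairs_round_trip(self, tmp_path):
        bedpe = abc.pairs_to_bedpe(pd.DataFrame(columns=abc.PAIR_COLS))
        path = tmp_path / "pairs.bedpe"
        io.write_bedpe(bedpe, path)
        assert path.read_text().startswith("#chrom1")
        assert io.read_bedpe(path).empty

    def test_one_pair_round_trip_and_anchors(self, tmp_path):
        pairs = pd.DataFrame([{
            "chrom": "chr1", "start": 990_000, "end": 990_250,
            "gene_id": "g1", "tss": 1_000_000, "distance": 9_875,
            "activity": 5.0, "contact": 1e-4, "score": 0.7}])
        bedpe = abc.pairs_to_bedpe(pairs)
        path = tmp_path / "pairs.bedpe"
        io.write_bedpe(bedpe, path)
        back = io.read_bedpe(path)
        assert len(back) == 1
        row = back.iloc[0]
        assert row["chrom1"] == row["chrom2"] == "chr1"
        assert (row["start1"], row["end1"]) != (row["start2"], row["end2"])
        assert (row["start2"], row["end2"]) == (999_750, 1_000_250)
        assert row["score"] == pytest.approx(0.7)


def test_true_enhancer_recall_on_synthetic_data(default_dataset, default_run):
    """Planted NPC-active enhancer->gene links are recovered at the default
    score threshold with recall >= 0.8."""
    outdir, _ = default_run
    pairs = io.read_bedpe(outdir / "abc_pairs.bedpe")
    truth = default_dataset.truth
    targets = truth.enhancer_targets
    targets = targets.loc[targets["active"].isin(["B", "both"])]
    reg = truth.regions.set_index("region_id")
    recovered = 0
    for _, row in targets.iterrows():
        r = reg.loc[row["region_id"]]
        hit = pairs.loc[(pairs["name"] == row["gene_id"])
                        & (pairs["chrom1"] == r["chrom"])
                        & (pairs["start1"] < r["end"])
                        & (pairs["end1"] > r["start"])]
        recovered += len(hit) > 0
    assert len(targets) > 0
    assert recovered / len(targets) >= 0.8
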