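"""Peak-to-gene linkage, induction genes, primed promoters, TSS fractions.

A peak links to a gene when the TSS lies within a window (default +/- 5 kb)
of the peak interval, measured strand-independently as the distance from
the TSS to the nearest covered base (0 when the TSS is inside the peak).
Cluster I/N links must additionally show a >2-fold pseudocounted signal
change in their cluster's direction; Cluster C links are exempt.

Induction genes are Cluster-C-linked genes whose mean expression rises by
at least ``min_lfc`` log2 units from condition A to B.  Primed promoter
peaks are Cluster C peaks whose nearest linked gene is an induction gene:
regions already open in the stem state whose gene fires on differentiation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from epiprime import regions

DEFAULT_WINDOW = 5_000
LINK_COLS = ["peak_index", "gene_id", "distance", "label"]


def link_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame,
                        window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """One row per (peak, gene) pair with TSS-to-peak distance <= window.

    ``peak_index`` refers to the positional row in ``peaks``; label and
    per-condition signal columns present on the peaks are carried through.
    """
    carried = [c for c in ("label", "signal_a", "signal_b") if c in peaks.columns]
    rows = []
    peaks = peaks.reset_index(drop=True)
    for chrom, pk in peaks.groupby("chrom"):
        gn = genes.loc[genes["chrom"] == chrom]
        if gn.empty:
            continue
        tss = gn["tss"].to_numpy()[:, None]
        dist = regions.point_to_interval_distance(
            tss, pk["start"].to_numpy(), pk["end"].to_numpy())
        gi, pi = np.nonzero(dist <= window)
        if len(gi) == 0:
            continue
        sub = pd.DataFrame({
            "peak_index": pk.index.to_numpy()[pi],
            "gene_id": gn["gene_id"].to_numpy()[gi],
            "distance": dist[gi, pi].astype(int),
        })
        for c in carried:
            sub[c] = pk[c].to_numpy()[pi]
        rows.append(sub)
    if not rows:
        out = pd.DataFrame({"peak_index": pd.Series(dtype=int),
                            "gene_id": pd.Series(dtype=str),
                            "distance": pd.Series(dtype=int)})
        for c in carried:
            out[c] = pd.Series(dtype=peaks[c].dtype)
        return out
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["peak_index", "gene_id"], ignore_index=True)


def fold_change_filter(links: pd.DataFrame, min_fc: float = 2.0,
                       pseudocount: float = 1.0) -> pd.DataFrame:
    """Keep Cluster I/N links only when the pseudocounted signal ratio in
    the cluster's direction exceeds ``min_fc``; Cluster C links pass
    unfiltered.  Links on unassigned peaks are dropped."""
    for col in ("label", "signal_a", "signal_b"):
        if col not in links.columns:
            raise ValueError(f"links table missing column {col!r}")
    if links.empty:
        return links.copy()
    pc = pseudocount
    ratio_a = (links["signal_a"] + pc) / (links["signal_b"] + pc)
    ratio_b = (links["signal_b"] + pc) / (links["signal_a"] + pc)
    keep = np.where(
        links["label"] == "C", True,
        np.where(links["label"] == "I", ratio_a > min_fc,
                 np.where(links["label"] == "N", ratio_b > min_fc, False)))
    return links.loc[keep].reset_index(drop=True)


def mean_log2_change(expression: pd.DataFrame, samples_a, samples_b,
                     pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log2((mean TPM_B + pc) / (mean TPM_A + pc))."""
    mean_a = expression[list(samples_a)].mean(axis=1)
    mean_b = expression[list(samples_b)].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount))


def induction_genes(links: pd.DataFrame, expression: pd.DataFrame,
                    samples_a, samples_b, min_lfc: float = 1.0,
                    pseudocount: float = 1.0) -> tuple[list[str], list[str]]:
    """Genes linked to a Cluster C peak whose expression rises >= min_lfc.

    Returns (sorted induced gene ids, gene ids missing from the expression
    matrix -- recorded and skipped).
    """
    if "label" in links.columns:
        links = links.loc[links["label"] == "C"]
    candidates = sorted(set(links["gene_id"]))
    missing = [g for g in candidates if g not in expression.index]
    present = [g for g in candidates if g in expression.index]
    if not present:
        return [], missing
    lfc = mean_log2_change(expression.loc[present], samples_a, samples_b,
                           pseudocount)
    induced = sorted(lfc.index[lfc >= min_lfc])
    return induced, missing


def primed_promoter_peaks(calls: pd.DataFrame, induced: set[str] | list[str],
                          links: pd.DataFrame) -> pd.DataFrame:
    """Cluster C peaks whose nearest linked gene is an induction gene.

    Nearest = minimal TSS distance among the peak's links; on ties every
    tied gene is consulted and the peak is kept if any is induced.
    """
    induced = set(induced)
    if links.empty or not induced:
        return calls.iloc[0:0].copy()
    c_links = links.loc[links["label"] == "C"] if "label" in links.columns else links
    if c_links.empty:
        return calls.iloc[0:0].copy()
    nearest = c_links.groupby("peak_index")["distance"].transform("min")
    at_min = c_links.loc[c_links["distance"] == nearest]
    keep_idx = sorted(
        set(at_min.loc[at_min["gene_id"].isin(induced), "peak_index"]))
    out = calls.reset_index(drop=True).iloc[keep_idx].copy()
    if "label" in out.columns:
        out = out.loc[out["label"] == "C"]
    return out


def tss_fraction(peaks: pd.DataFrame, genes: pd.DataFrame,
                 window: int = DEFAULT_WINDOW) -> float:
    """Fraction of peaks lying within +/- window of any TSS."""
    if peaks.empty:
        raise ValueError("tss_fraction of an empty peak set is undefined")
    near = np.zeros(len(peaks), dtype=bool)
    peaks = peaks.reset_index(drop=True)
    for chrom, pk in peaks.groupby("chrom"):
        gn = genes.loc[genes["chrom"] == chrom]
        if gn.empty:
            continue
        tss = gn["tss"].to_numpy()[:, None]
        dist = regions.point_to_interval_distance(
            tss, pk["start"].to_numpy(), pk["end"].to_numpy())
        near[pk.index.to_numpy()] = (dist <= window).any(axis=0)
    return float(near.mean())
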