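"""Open/closed chromatin dichotomization against a pseudo-input background.

The peak-recall procedure re-evaluates every consensus peak in *both*
conditions instead of trusting per-condition peak calls:

1. all called peaks from both conditions are merged into a foreground set;
2. fragments overlapping the foreground are removed, leaving a pseudo-input
   that empirically samples the background;
3. background regions are scored in both conditions (RP10M: midpoint count
   scaled by 1e7 / total unique fragments);
4. the background signal threshold is the empirical (1 - FDR) quantile of
   the pooled background distribution (default FDR 0.5%);
5. each consensus peak is labelled C (open in both), I (condition A only),
   N (condition B only) or unassigned (neither) by comparing its RP10M
   signal in each condition against the threshold (strictly greater than).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epiprime import regions

DEFAULT_FDR = 0.005
RP10M_SCALE = 1e7
LABELS = ("C", "I", "N", "unassigned")


def merge_all_peaks(peaksets) -> pd.DataFrame:
    """Union of all per-condition peak intervals, coalesced and sorted."""
    if isinstance(peaksets, pd.DataFrame):
        peaksets = [peaksets]
    nonempty = [ps[["chrom", "start", "end"]] for ps in peaksets if len(ps)]
    if not nonempty:
        return regions.empty_intervals()
    return regions.merge_intervals(pd.concat(nonempty, ignore_index=True))


def make_pseudo_input(fragments: pd.DataFrame, merged: pd.DataFrame) -> pd.DataFrame:
    """Fragments with zero overlap (interval overlap, not midpoint) with
    the merged foreground peak set."""
    if fragments.empty or merged.empty:
        return fragments.copy()
    hit = regions.overlaps_any(fragments, merged)
    return fragments.loc[~hit].reset_index(drop=True)


def call_peaks_simple(fragments: pd.DataFrame, genome: dict[str, int],
                      window: int = 300, step: int = 150,
                      q: float = 0.05) -> pd.DataFrame:
    """Sliding-window Poisson peak caller.

    Windows of ``window`` bp every ``step`` bp are tested against a global
    Poisson background (lambda = total midpoints x window / genome length)
    and Benjamini-Hochberg corrected at ``q``.  Overlapping significant
    windows merge into one peak whose summit is the centre of its
    highest-count window.  This is a deliberately simple, deterministic
    stand-in for a full peak caller, adequate for the synthetic data the
    package targets.
    """
    if not genome:
        raise ValueError("empty genome")
    cols = ["chrom", "start", "end", "name", "score", "strand", "signal", "summit"]
    empty = pd.DataFrame({c: [] for c in cols}).astype(
        {"start": np.int64, "end": np.int64, "score": float,
         "signal": float, "summit": np.int64})
    if fragments.empty:
        return empty
    total_len = regions.total_genome_length(genome)
    mids = regions.midpoints(fragments)
    total_mids = sum(len(v) for v in mids.values())

    win_chrom, win_start, win_end, win_count = [], [], [], []
    for chrom, length in genome.items():
        starts = np.arange(0, max(length - window, 0) + 1, step, dtype=np.int64)
        if len(starts) == 0:
            starts = np.array([0], dtype=np.int64)
        ends = np.minimum(starts + window, length)
        m = mids.get(chrom, np.empty(0, dtype=np.int64))
        counts = np.searchsorted(m, ends) - np.searchsorted(m, starts)
        win_chrom.append(np.full(len(starts), chrom, dtype=object))
        win_start.append(starts)
        win_end.append(ends)
        win_count.append(counts)
    chroms = np.concatenate(win_chrom)
    starts = np.concatenate(win_start)
    ends = np.concatenate(win_end)
    counts = np.concatenate(win_count)

    lam = total_mids * (ends - starts) / total_len
    pvals = stats.poisson.sf(counts - 1, lam)
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    if not reject.any():
        return empty

    sig = pd.DataFrame({"chrom": chroms[reject], "start": starts[reject],
                        "end": ends[reject], "count": counts[reject],
                        "pval": pvals[reject]})
    peaks = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        run = np.concatenate([[0], np.cumsum(s[1:] >= np.maximum.accumulate(e)[:-1])])
        for _, sub in grp.assign(run=run).groupby("run"):
            best = sub.loc[sub["count"].idxmax()]
            minp = max(float(sub["pval"].min()), 1e-300)
            peaks.append((chrom, int(sub["start"].min()), int(sub["end"].max()),
                          -10.0 * math.log10(minp), float(best["count"]),
                          int((best["start"] + best["end"]) // 2)))
    out = pd.DataFrame(peaks, columns=["chrom", "start", "end", "score",
                                       "signal", "summit"])
    out.insert(3, "name", [f"peak_{i}" for i in range(len(out))])
    out.insert(5, "strand", ".")
    return out[cols]


def normalize_rp10m(fragments: pd.DataFrame, intervals: pd.DataFrame,
                    total_unique: int | None = None) -> np.ndarray:
    """Per-interval RP10M: midpoint count x 1e7 / total unique fragments."""
    total = len(fragments) if total_unique is None else int(total_unique)
    if total <= 0:
        raise ValueError("total_unique must be positive for RP10M normalization")
    counts = regions.count_midpoints(fragments, intervals)
    return counts * (RP10M_SCALE / total)


def background_windows(genome: dict[str, int], merged: pd.DataFrame,
                       width: int = 500) -> pd.DataFrame:
    """Non-overlapping width-bp tiling windows disjoint from the merged
    foreground peaks; these play the role of background peaks when the
    pseudo-input is too uniform for the caller to report any."""
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, max(length - width, 0) + 1, width, dtype=np.int64)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": starts + width}))
    win = pd.concat(rows, ignore_index=True)
    if len(merged):
        win = win.loc[~regions.overlaps_any(win, merged)].reset_index(drop=True)
    return win


def estimate_background_threshold(values, fdr: float = DEFAULT_FDR) -> float:
    """Empirical (1 - fdr) quantile of pooled background signals.

    Uses the "higher" order statistic sorted[ceil((1 - fdr) * n)] (1-based)
    so that the fraction of background values strictly above the threshold
    never exceeds the nominal FDR.  fdr = 0 returns the maximum.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty background set")
    if not 0 <= fdr < 1:
        raise ValueError("fdr must be in [0, 1)")
    if values.size < 200:
        warnings.warn(
            f"only {values.size} background values; threshold estimate is noisy",
            stacklevel=2,
        )
    n = values.size
    k = math.ceil((1.0 - fdr) * n - 1e-12)
    k = min(max(k, 1), n)
    return float(np.sort(values)[k - 1])


def classify_openness(consensus: pd.DataFrame, signal_a, signal_b,
                      threshold: float) -> tuple[pd.DataFrame, dict]:
    """Label each consensus peak C / I / N / unassigned.

    Open in a condition means RP10M signal strictly greater than the
    background threshold.  Returns the annotated table and a summary with
    per-label counts (a partition of the consensus set).
    """
    signal_a = np.asarray(signal_a, dtype=float)
    signal_b = np.asarray(signal_b, dtype=float)
    if len(signal_a) != len(consensus) or len(signal_b) != len(consensus):
        raise ValueError("signals and consensus peaks must align")
    open_a = signal_a > threshold
    open_b = signal_b > threshold
    label = np.where(open_a & open_b, "C",
                     np.where(open_a, "I",
                              np.where(open_b, "N", "unassigned")))
    calls = consensus.copy()
    calls["signal_a"] = signal_a
    calls["signal_b"] = signal_b
    calls["label"] = label
    counts = Counter(label)
    summary = {
        "threshold": float(threshold),
        "counts": {lab: int(counts.get(lab, 0)) for lab in LABELS},
        "total": int(len(calls)),
    }
    return calls, summary
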