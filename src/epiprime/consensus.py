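"""Cross-sample consensus peak construction by iterative overlap removal.

Peaks from all samples are normalized to score-per-million (spm) within
each sample, resized to a fixed width around their summits, pooled, and
ranked by spm.  The top-ranked peak is retained and every remaining peak
overlapping it (>= 1 bp) is discarded; this repeats until the pool is
empty.  Retained peaks whose spm falls below the cutoff (default 2) are
then removed.  The result is a fixed-width, pairwise non-overlapping
consensus peak set comparable across samples.
"""

from __future__ import annotations

from bisect import bisect_left

import numpy as np
import pandas as pd

from epiprime import regions

DEFAULT_WIDTH = 500
DEFAULT_SPM_CUTOFF = 2.0


def score_per_million(peaks: pd.DataFrame) -> pd.DataFrame:
    """Add an ``spm`` column: score_i * 1e6 / sum(scores), per sample.

    With a ``sample_id`` column normalization is within sample so that each
    sample's spm values sum to 1e6; without one the whole table is treated
    as a single sample.
    """
    peaks = peaks.copy()
    if peaks.empty:
        peaks["spm"] = pd.Series(dtype=float)
        return peaks
    if (peaks["score"] < 0).any():
        raise ValueError("peak scores must be non-negative")
    if "sample_id" in peaks.columns:
        totals = peaks.groupby("sample_id")["score"].transform("sum")
    else:
        totals = pd.Series(peaks["score"].sum(), index=peaks.index)
    if (totals <= 0).any():
        raise ValueError("cannot normalize a sample whose scores sum to zero")
    peaks["spm"] = peaks["score"] * 1e6 / totals
    return peaks


def resize_to_width(peaks: pd.DataFrame, width: int,
                    genome: dict[str, int] | None = None) -> pd.DataFrame:
    """Summit-centered fixed-width intervals [summit - w/2, summit + w/2).

    Intervals are clipped at chromosome bounds (0 and, when a genome is
    given, the chromosome length); clipped peaks are flagged.  A summit
    outside its chromosome is an error.
    """
    if width <= 0 or width % 2:
        raise ValueError("width must be positive and even")
    peaks = peaks.copy()
    if peaks.empty:
        peaks["clipped"] = pd.Series(dtype=bool)
        return peaks
    summit = peaks["summit"].astype(np.int64)
    if (summit < 0).any():
        raise ValueError("summit outside chromosome (negative coordinate)")
    half = width // 2
    start = summit - half
    end = summit + half
    clipped = start < 0
    start = start.clip(lower=0)
    if genome is not None:
        lengths = peaks["chrom"].map(genome)
        if lengths.isna().any():
            missing = peaks.loc[lengths.isna(), "chrom"].iloc[0]
            raise ValueError(f"chromosome {missing!r} absent from genome")
        if (summit >= lengths).any():
            raise ValueError("summit outside chromosome (beyond length)")
        clipped = clipped | (end > lengths)
        end = np.minimum(end, lengths.astype(np.int64))
    peaks["start"] = start
    peaks["end"] = end
    peaks["clipped"] = clipped.to_numpy()
    return peaks


def _greedy_retain(pooled: pd.DataFrame) -> np.ndarray:
    """Positional indices retained by spm-ranked overlap removal.

    Equal-spm ties break toward the smaller (chrom, start) so the result
    is deterministic.  Kept intervals per chromosome stay in sorted lists;
    because kept intervals are pairwise disjoint, only the neighbours of
    the insertion point can overlap a candidate.
    """
    order = pooled.sort_values(["spm", "chrom", "start", "end"],
                               ascending=[False, True, True, True],
                               kind="mergesort").index.to_numpy()
    kept_starts: dict[str, list] = {}
    kept_ends: dict[str, list] = {}
    retained = []
    chroms = pooled["chrom"].to_numpy()
    starts = pooled["start"].to_numpy()
    ends = pooled["end"].to_numpy()
    for i in order:
        chrom, s, e = chroms[i], starts[i], ends[i]
        ks = kept_starts.setdefault(chrom, [])
        ke = kept_ends.setdefault(chrom, [])
        pos = bisect_left(ks, s)
        if pos > 0 and ke[pos - 1] > s:
            continue
        if pos < len(ks) and ks[pos] < e:
            continue
        ks.insert(pos, s)
        ke.insert(pos, e)
        retained.append(i)
    return np.array(retained, dtype=int)


def iterative_merge(peaksets, width: int = DEFAULT_WIDTH,
                    spm_cutoff: float = DEFAULT_SPM_CUTOFF,
                    genome: dict[str, int] | None = None) -> pd.DataFrame:
    """Build the consensus peak set from per-sample peak tables.

    Parameters
    ----------
    peaksets
        A list of per-sample peak tables (chrom/start/end/summit/score,
        optionally sample_id) or a single pooled table.  spm is computed
        per sample before pooling unless already present.
    width
        Fixed width applied around each summit before ranking.
    spm_cutoff
        Retained peaks with spm strictly below this are dropped after
        overlap removal.
    """
    if isinstance(peaksets, pd.DataFrame):
        peaksets = [peaksets]
    normed = []
    for ps in peaksets:
        if ps.empty:
            continue
        normed.append(ps if "spm" in ps.columns else score_per_million(ps))
    if not normed:
        return regions.empty_intervals(["summit", "score", "spm", "sample_id", "name"])
    pooled = pd.concat(normed, ignore_index=True)
    pooled = resize_to_width(pooled, width, genome=genome)
    retained = _greedy_retain(pooled)
    out = pooled.loc[retained]
    out = out.loc[out["spm"] >= spm_cutoff]
    out = regions.sort_intervals(out)
    out["name"] = [f"consensus_{i}" for i in range(len(out))]
    return out
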