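"""Interval arithmetic on 0-based half-open genomic coordinates.

Every interval table in the package is a :class:`pandas.DataFrame` with at
least the columns ``chrom`` (str), ``start`` and ``end`` (int, half-open).
Two intervals overlap iff they share >= 1 bp on the same chromosome;
bookended intervals ([100,200) and [200,300)) do not overlap but may be
coalesced by :func:`merge_intervals` when ``merge_adjacent`` is set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED3_COLS = ["chrom", "start", "end"]


def empty_intervals(extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = BED3_COLS + (extra_cols or [])
    df = pd.DataFrame({c: [] for c in cols})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Stable (chrom, start, end) sort with a fresh index."""
    return df.sort_values(["chrom", "start", "end"], kind="mergesort", ignore_index=True)


def validate_intervals(df: pd.DataFrame) -> None:
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df.loc[~(df["start"] < df["end"])].iloc[0]
        raise ValueError(f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")


def merge_intervals(df: pd.DataFrame, merge_adjacent: bool = True) -> pd.DataFrame:
    """Coalesce a set of intervals into a sorted, non-overlapping union.

    With ``merge_adjacent`` (default) intervals that touch end-to-start are
    also joined, so the result is the minimal covering set.
    """
    if df.empty:
        return empty_intervals()
    validate_intervals(df)
    df = sort_intervals(df[BED3_COLS])
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cummax_end = np.maximum.accumulate(ends)
        if merge_adjacent:
            new_run = starts[1:] > cummax_end[:-1]
        else:
            new_run = starts[1:] >= cummax_end[:-1]
        run_id = np.concatenate([[0], np.cumsum(new_run)])
        sub = pd.DataFrame({"start": starts, "end": ends, "run": run_id})
        agg = sub.groupby("run").agg(start=("start", "min"), end=("end", "max"))
        agg.insert(0, "chrom", chrom)
        out.append(agg)
    return pd.concat(out, ignore_index=True)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean array: does each query interval overlap (>=1 bp) any subject?"""
    result = np.zeros(len(query), dtype=bool)
    if query.empty or subject.empty:
        return result
    merged = merge_intervals(subject)
    by_chrom = {c: g for c, g in merged.groupby("chrom")}
    query = query.reset_index(drop=True)
    for chrom, grp in query.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        ss = by_chrom[chrom]["start"].to_numpy()
        se = by_chrom[chrom]["end"].to_numpy()
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        # last subject interval starting before the query end; merged
        # intervals are disjoint and sorted so this is the only candidate
        # reaching far enough right.
        idx = np.searchsorted(ss, qe, side="left") - 1
        hit = (idx >= 0) & (se[np.clip(idx, 0, None)] > qs)
        result[grp.index.to_numpy()] = hit
    return result


def count_overlaps(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Number of subject intervals overlapping each query interval.

    Subject intervals may overlap each other; counts use the classic
    sorted-starts minus sorted-ends trick.
    """
    result = np.zeros(len(query), dtype=int)
    if query.empty or subject.empty:
        return result
    query = query.reset_index(drop=True)
    for chrom, grp in query.groupby("chrom"):
        sub = subject.loc[subject["chrom"] == chrom]
        if sub.empty:
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        qs = grp["start"].to_numpy()
        qe = grp["end"].to_numpy()
        n = np.searchsorted(starts, qe, side="left") - np.searchsorted(ends, qs, side="right")
        result[grp.index.to_numpy()] = n
    return result


def midpoints(fragments: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome sorted fragment midpoints, as {chrom: int array}."""
    return {
        chrom: np.sort(((grp["start"] + grp["end"]) // 2).to_numpy())
        for chrom, grp in fragments.groupby("chrom")
    }


def count_midpoints(fragments: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Count fragment midpoints falling in each interval.

    A fragment "is in" an interval iff its midpoint (start+end)//2 lies in
    [start, end) -- the convention used for all signal quantification here.
    """
    counts = np.zeros(len(intervals), dtype=int)
    if fragments.empty or intervals.empty:
        return counts
    mids = midpoints(fragments)
    intervals = intervals.reset_index(drop=True)
    for chrom, grp in intervals.groupby("chrom"):
        if chrom not in mids:
            continue
        m = mids[chrom]
        lo = np.searchsorted(m, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(m, grp["end"].to_numpy(), side="left")
        counts[grp.index.to_numpy()] = hi - lo
    return counts


def point_to_interval_distance(points: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Distance (bp) from each point to an interval; 0 when the point is inside.

    Broadcasts: points shape (n,1) against interval arrays shape (m,) gives
    an (n, m) matrix.  For a half-open interval the nearest covered base on
    the right is end-1.
    """
    left = starts - points
    right = points - (ends - 1)
    return np.maximum(0, np.maximum(left, right))


def total_genome_length(genome: dict[str, int]) -> int:
    return int(sum(genome.values()))
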