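"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most naive way possible
(python loops, per-bp bitmaps, all-pairs scans) and shares no code with
the library paths it checks.
"""

import numpy as np
import pandas as pd


def greedy_merge_oracle(peaks, spm_cutoff=2.0):
    """O(n^2) spm-ranked overlap-removal merge on a pooled peak table.

    Expects chrom/start/end/spm columns (already resized and normalized).
    Ties on spm break toward smaller (chrom, start).  Returns the retained
    rows sorted by (chrom, start).
    """
    rows = peaks.to_dict("records")
    order = sorted(range(len(rows)),
                   key=lambda i: (-rows[i]["spm"], rows[i]["chrom"],
                                  rows[i]["start"], rows[i]["end"]))
    kept = []
    for i in order:
        r = rows[i]
        conflict = False
        for k in kept:
            if (k["chrom"] == r["chrom"] and k["start"] < r["end"]
                    and k["end"] > r["start"]):
                conflict = True
                break
        if not conflict:
            kept.append(r)
    kept = [k for k in kept if k["spm"] >= spm_cutoff]
    return sorted(kept, key=lambda k: (k["chrom"], k["start"], k["end"]))


def bitmap_union_oracle(intervals, genome):
    """Interval union computed by marking every covered bp in a bitmap."""
    out = []
    for chrom, length in genome.items():
        mask = np.zeros(length, dtype=bool)
        for _, row in intervals.loc[intervals["chrom"] == chrom].iterrows():
            mask[row["start"]:row["end"]] = True
        padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
        diff = np.diff(padded)
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            out.append((chrom, int(s), int(e)))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def tss_peak_distance_oracle(tss, start, end):
    """Distance from a TSS to a half-open peak interval, by scanning bases."""
    if start <= tss < end:
        return 0
    return min(abs(tss - start), abs(tss - (end - 1)))


def all_pairs_links_oracle(peaks, genes, window):
    """Every (peak, gene) pair within the window, by a double loop."""
    out = []
    for pi, p in peaks.reset_index(drop=True).iterrows():
        for _, g in genes.iterrows():
            if g["chrom"] != p["chrom"]:
                continue
            d = tss_peak_distance_oracle(g["tss"], p["start"], p["end"])
            if d <= window:
                out.append((pi, g["gene_id"], d))
    return sorted(out)


def overlap_pairs_oracle(queries, subjects):
    """For each query interval, the number of subjects sharing >= 1 bp."""
    counts = []
    for _, q in queries.iterrows():
        n = 0
        for _, s in subjects.iterrows():
            if (q["chrom"] == s["chrom"] and s["start"] < q["end"]
                    and s["end"] > q["start"]):
                n += 1
        counts.append(n)
    return np.array(counts)


def random_peakset(rng, n, genome, width_lo=200, width_hi=800):
    """Random per-sample peak table with summits and positive scores."""
    chroms = list(genome)
    rows = []
    for i in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        length = genome[chrom]
        start = int(rng.integers(0, length - width_hi))
        width = int(rng.integers(width_lo, width_hi))
        end = start + width
        summit = int(rng.integers(start, end))
        rows.append((chrom, start, end, f"p{i}", float(rng.integers(1, 1000)),
                     ".", 0.0, summit))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand", "signal", "summit"])
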