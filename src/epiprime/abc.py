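"""Activity-by-Contact enhancer-gene scoring.

Candidate elements are 250 bp summit-centered windows ranked by ATAC
fragment count (top 150,000 kept), blacklist-filtered, and merged when
overlapping.  Element activity is the geometric mean of ATAC and H3K27ac
counts, A = sqrt(atac x k27ac).  Contact C follows either a power-law
distance decay (d + d0)^(-gamma), the standard fallback when no contact
map is available, or a binned contact table.  For a gene g the score of
element e is

    ABC(e, g) = A_e C_e / sum over elements e' within the window of A_e' C_e'

so per-gene scores sum to one; pairs at or above the threshold (default
0.02) are reported.  The gene's own promoter element (TSS +/- 250 bp)
participates in the denominator but promoter elements are not themselves
reported as enhancer-gene pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epiprime import consensus, io, regions

log = logging.getLogger(__name__)

DEFAULT_WIDTH = 250
DEFAULT_TOP_N = 150_000
DEFAULT_WINDOW = 5_000_000
DEFAULT_THRESHOLD = 0.02
DEFAULT_GAMMA = 1.0
DEFAULT_D0 = 5_000
PROMOTER_HALFWIDTH = 250

PAIR_COLS = ["chrom", "start", "end", "gene_id", "tss", "distance",
             "activity", "contact", "score"]


@dataclass
class ContactModel:
    """Distance-to-contact map, power-law or binned-table mode.

    In table mode ``table`` holds uniformly spaced ``bin_start`` values
    (first bin at 0) and a ``contact`` per bin; a distance beyond the last
    bin is an error.  Contact must be non-increasing in distance.
    """

    mode: str = "powerlaw"
    gamma: float = DEFAULT_GAMMA
    d0: int = DEFAULT_D0
    table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.mode not in ("powerlaw", "table"):
            raise ValueError(f"unknown contact mode {self.mode!r}")
        if self.mode == "powerlaw":
            if self.gamma < 0 or self.d0 <= 0:
                raise ValueError("powerlaw mode needs gamma >= 0 and d0 > 0")
        else:
            t = self.table
            if t is None or len(t) == 0:
                raise ValueError("table mode needs a non-empty contact table")
            starts = t["bin_start"].to_numpy()
            if starts[0] != 0 or (np.diff(starts) <= 0).any():
                raise ValueError("contact bins must start at 0 and increase")
            if (np.diff(t["contact"].to_numpy()) > 0).any():
                raise ValueError("contact must be non-increasing in distance")
            if (t["contact"].to_numpy() <= 0).any():
                raise ValueError("contact values must be strictly positive")

    def contact(self, distance) -> np.ndarray:
        """Contact frequency at each distance (bp, >= 0)."""
        d = np.asarray(distance, dtype=float)
        if (d < 0).any():
            raise ValueError("distance must be non-negative")
        if self.mode == "powerlaw":
            return (d + self.d0) ** (-self.gamma)
        starts = self.table["bin_start"].to_numpy(dtype=float)
        values = self.table["contact"].to_numpy(dtype=float)
        spacing = starts[1] - starts[0] if len(starts) > 1 else np.inf
        limit = starts[-1] + spacing
        if (d >= limit).any():
            raise ValueError(
                f"distance {d.max():.0f} beyond contact table range ({limit:.0f})")
        idx = np.searchsorted(starts, d, side="right") - 1
        return values[idx]


def contact(model: ContactModel, distance) -> np.ndarray:
    return model.contact(distance)


def element_activity(atac_counts, k27ac_counts) -> np.ndarray:
    """Geometric-mean activity sqrt(atac x k27ac); zero if either is zero."""
    a = np.asarray(atac_counts, dtype=float)
    k = np.asarray(k27ac_counts, dtype=float)
    if (a < 0).any() or (k < 0).any():
        raise ValueError("counts must be non-negative")
    return np.sqrt(a * k)


def make_candidate_elements(peaks: pd.DataFrame, fragments: pd.DataFrame,
                            top_n: int = DEFAULT_TOP_N,
                            width: int = DEFAULT_WIDTH,
                            blacklist: pd.DataFrame | None = None,
                            genome: dict[str, int] | None = None) -> pd.DataFrame:
    """Summit-centered width-bp elements, ranked by ATAC midpoint count.

    The top ``top_n`` elements are kept, any overlapping the blacklist
    removed, and remaining mutually overlapping elements merged; merged
    spans are re-counted over the combined interval rather than summing
    member counts, so shared fragments are not double-counted.
    """
    if peaks.empty:
        return regions.empty_intervals(["atac_count"])
    elems = consensus.resize_to_width(peaks, width, genome=genome)
    elems = elems[["chrom", "start", "end"]].copy()
    elems["atac_count"] = regions.count_midpoints(fragments, elems)
    elems = elems.sort_values(["atac_count", "chrom", "start"],
                              ascending=[False, True, True],
                              kind="mergesort").head(top_n)
    if blacklist is not None and len(blacklist):
        elems = elems.loc[~regions.overlaps_any(elems, blacklist)]
    if elems.empty:
        return regions.empty_intervals(["atac_count"])
    merged = regions.merge_intervals(elems, merge_adjacent=False)
    merged["atac_count"] = regions.count_midpoints(fragments, merged)
    return merged


def promoter_elements(genes: pd.DataFrame, atac_fragments: pd.DataFrame,
                      k27_fragments: pd.DataFrame,
                      halfwidth: int = PROMOTER_HALFWIDTH) -> pd.DataFrame:
    """TSS +/- halfwidth promoter elements with activities, one per gene."""
    prom = pd.DataFrame({
        "chrom": genes["chrom"].to_numpy(),
        "start": (genes["tss"] - halfwidth).clip(lower=0).astype(np.int64),
        "end": (genes["tss"] + halfwidth).astype(np.int64),
        "owner_gene": genes["gene_id"].to_numpy(),
    })
    prom["atac_count"] = regions.count_midpoints(atac_fragments, prom)
    prom["k27_count"] = regions.count_midpoints(k27_fragments, prom)
    prom["activity"] = element_activity(prom["atac_count"], prom["k27_count"])
    prom["is_promoter"] = True
    return prom


def annotate_elements(elements: pd.DataFrame, k27_fragments: pd.DataFrame) -> pd.DataFrame:
    """Attach H3K27ac counts and activity to candidate elements."""
    out = elements.copy()
    out["k27_count"] = regions.count_midpoints(k27_fragments, out)
    out["activity"] = element_activity(out["atac_count"], out["k27_count"])
    out["is_promoter"] = False
    out["owner_gene"] = ""
    return out


def abc_scores(elements: pd.DataFrame, gene, model: ContactModel,
               window: int = DEFAULT_WINDOW,
               threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Score all elements within +/- window of one gene's TSS.

    ``gene`` is a mapping with gene_id, chrom and tss.  ``elements`` needs
    chrom/start/end/activity and optionally is_promoter/owner_gene flags.
    Scores over the window sum to 1; rows with score >= threshold are
    returned, excluding promoter elements (they only contribute to the
    denominator).  All-zero activity in the window yields no pairs and a
    log warning.
    """
    gene_id, chrom, tss = gene["gene_id"], gene["chrom"], int(gene["tss"])
    near = elements.loc[elements["chrom"] == chrom].copy()
    if near.empty:
        return pd.DataFrame(columns=PAIR_COLS)
    mid = (near["start"].to_numpy() + near["end"].to_numpy()) // 2
    dist = np.abs(mid - tss)
    near = near.loc[dist <= window]
    dist = dist[dist <= window]
    if near.empty:
        return pd.DataFrame(columns=PAIR_COLS)
    activity = near["activity"].to_numpy(dtype=float)
    cvals = model.contact(dist)
    weights = activity * cvals
    total = weights.sum()
    if total <= 0:
        log.warning("all-zero activity within window of %s; no pairs", gene_id)
        return pd.DataFrame(columns=PAIR_COLS)
    scores = weights / total
    out = pd.DataFrame({
        "chrom": near["chrom"].to_numpy(),
        "start": near["start"].to_numpy(),
        "end": near["end"].to_numpy(),
        "gene_id": gene_id,
        "tss": tss,
        "distance": dist.astype(int),
        "activity": activity,
        "contact": cvals,
        "score": scores,
    })
    if "is_promoter" in near.columns:
        out = out.loc[~near["is_promoter"].to_numpy(dtype=bool)]
    return out.loc[out["score"] >= threshold].reset_index(drop=True)


def score_all_genes(elements: pd.DataFrame, genes: pd.DataFrame,
                    atac_fragments: pd.DataFrame, k27_fragments: pd.DataFrame,
                    model: ContactModel, window: int = DEFAULT_WINDOW,
                    threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """ABC pairs for every gene, with promoter accounting.

    Candidate elements overlapping any promoter element are replaced by
    the canonical TSS +/- 250 bp promoter elements, which join every
    nearby gene's denominator but are never emitted as enhancers.
    """
    ann = annotate_elements(elements, k27_fragments)
    prom = promoter_elements(genes, atac_fragments, k27_fragments)
    if len(prom):
        ann = ann.loc[~regions.overlaps_any(ann, prom)]
    pool = pd.concat([ann, prom], ignore_index=True)
    pairs = []
    for _, gene in genes.iterrows():
        scored = abc_scores(pool, gene, model, window=window, threshold=threshold)
        if len(scored):
            pairs.append(scored)
    if not pairs:
        return pd.DataFrame(columns=PAIR_COLS)
    out = pd.concat(pairs, ignore_index=True)
    return out.sort_values(["chrom", "start", "gene_id"], ignore_index=True)


def pairs_to_bedpe(pairs: pd.DataFrame,
                   promoter_halfwidth: int = PROMOTER_HALFWIDTH) -> pd.DataFrame:
    """10-column BEDPE: anchor1 = element, anchor2 = promoter interval."""
    if pairs.empty:
        return pd.DataFrame(columns=io.BEDPE_COLS)
    out = pd.DataFrame({
        "chrom1": pairs["chrom"],
        "start1": pairs["start"].astype(np.int64),
        "end1": pairs["end"].astype(np.int64),
        "chrom2": pairs["chrom"],
        "start2": (pairs["tss"] - promoter_halfwidth).clip(lower=0).astype(np.int64),
        "end2": (pairs["tss"] + promoter_halfwidth).astype(np.int64),
        "name": pairs["gene_id"],
        "score": pairs["score"],
        "strand1": ".",
        "strand2": ".",
    })
    return out.sort_values(["chrom1", "start1", "name"], ignore_index=True)
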