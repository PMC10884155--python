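"""TF ChIP-seq intersection with enhancer-promoter pairs and promoters.

Given a TF's ChIP peak set and an ABC BEDPE table, a pair is "TF-bound"
when at least one ChIP peak overlaps (>= 1 bp) the selected anchor
(default: the enhancer anchor).  Direct promoter binding is called when a
ChIP peak overlaps TSS +/- promoter_window.  Deduplicated target-gene
lists with evidence class (enhancer / promoter / both) are exported for
downstream ontology tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from epiprime import regions

DEFAULT_PROMOTER_WINDOW = 2_000


def intersect_pairs(chip: pd.DataFrame, pairs: pd.DataFrame,
                    anchor: str = "enhancer") -> pd.DataFrame:
    """Pairs whose selected anchor overlaps >= 1 ChIP peak.

    ``anchor`` is "enhancer" (anchor1 only) or "either".  The returned
    table is a subset of the input pairs with ``n_chip_enh`` and (for
    "either") ``n_chip_prom`` columns recording overlapping peak counts.
    """
    if anchor not in ("enhancer", "either"):
        raise ValueError(f"anchor must be 'enhancer' or 'either', got {anchor!r}")
    out = pairs.copy().reset_index(drop=True)
    if out.empty:
        out["n_chip_enh"] = pd.Series(dtype=int)
        return out
    enh = out[["chrom1", "start1", "end1"]].rename(
        columns={"chrom1": "chrom", "start1": "start", "end1": "end"})
    out["n_chip_enh"] = regions.count_overlaps(enh, chip)
    keep = out["n_chip_enh"] > 0
    if anchor == "either":
        prom = out[["chrom2", "start2", "end2"]].rename(
            columns={"chrom2": "chrom", "start2": "start", "end2": "end"})
        out["n_chip_prom"] = regions.count_overlaps(prom, chip)
        keep = keep | (out["n_chip_prom"] > 0)
    out = out.loc[keep]
    return out.sort_values(["chrom1", "start1", "name"], ignore_index=True)


def promoter_binding(chip: pd.DataFrame, genes: pd.DataFrame,
                     promoter_window: int = DEFAULT_PROMOTER_WINDOW) -> list[str]:
    """Genes whose promoter window [TSS - w, TSS + w) overlaps a ChIP peak."""
    if genes.empty or chip.empty:
        return []
    windows = pd.DataFrame({
        "chrom": genes["chrom"].to_numpy(),
        "start": (genes["tss"] - promoter_window).clip(lower=0).astype(np.int64),
        "end": (genes["tss"] + promoter_window).astype(np.int64),
    })
    hit = regions.overlaps_any(windows, chip)
    return sorted(genes.loc[hit, "gene_id"])


def export_target_genes(bound_pairs: pd.DataFrame,
                        promoter_bound: list[str]) -> pd.DataFrame:
    """Deduplicated target-gene list with evidence class.

    Evidence is "enhancer" (TF-bound enhancer-promoter pair), "promoter"
    (direct promoter binding) or "both"; output is sorted by gene_id and
    suitable as input to external ontology tools.
    """
    enh_genes = set(bound_pairs["name"]) if len(bound_pairs) else set()
    prom_genes = set(promoter_bound)
    rows = []
    for gene in sorted(enh_genes | prom_genes):
        if gene in enh_genes and gene in prom_genes:
            ev = "both"
        elif gene in enh_genes:
            ev = "enhancer"
        else:
            ev = "promoter"
        rows.append((gene, ev))
    return pd.DataFrame(rows, columns=["gene_id", "evidence"])
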