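"""Knockdown-response classification into four WT-response x KD-effect clusters.

From a gene x sample TPM matrix covering WT/KD genotypes at ESC and NPC
stages, each gene's wild-type differentiation response is the pseudocounted
log2 ratio of mean NPC to mean ESC TPM: induced (>= lfc threshold),
repressed (<= -threshold) or flat.  For non-flat genes the knockdown
attenuation r = kd_delta / wt_delta measures how much of the wild-type
log-change the knockdown line achieves; a gene is "affected" when r falls
below the cutoff (default 0.5, i.e. the KD line reaches less than half the
WT change in the same direction).  Clusters: 1 = WT up, KD unaffected;
2 = WT up, KD affected; 3 = WT down, KD unaffected; 4 = WT down, KD
affected; flat genes get cluster "none".

The explicit attenuation rule replaces an unparameterized hierarchical
clustering of expression profiles; agglomerative clustering of the
(wt_delta, kd_delta) profiles is available as a cross-check mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_LFC = 1.0
DEFAULT_ATTENUATION = 0.5
DEFAULT_PSEUDOCOUNT = 1.0


def _samples(sheet: pd.DataFrame, genotype: str, stage: str) -> list[str]:
    sel = sheet.loc[(sheet["genotype"] == genotype) & (sheet["stage"] == stage),
                    "sample"].tolist()
    if not sel:
        raise ValueError(f"no {genotype} {stage} samples in sheet")
    return sel


def _delta(expr: pd.DataFrame, esc: list[str], npc: list[str],
           pc: float) -> pd.Series:
    return np.log2((expr[npc].mean(axis=1) + pc) / (expr[esc].mean(axis=1) + pc))


def define_wt_response(expression: pd.DataFrame, sheet: pd.DataFrame,
                       lfc_threshold: float = DEFAULT_LFC,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-gene WT differentiation response: induced / repressed / flat."""
    esc = _samples(sheet, "WT", "ESC")
    npc = _samples(sheet, "WT", "NPC")
    wt_delta = _delta(expression, esc, npc, pseudocount)
    wt_class = np.where(wt_delta >= lfc_threshold, "induced",
                        np.where(wt_delta <= -lfc_threshold, "repressed", "flat"))
    return pd.DataFrame({"gene_id": expression.index,
                         "wt_delta": wt_delta.to_numpy(),
                         "wt_class": wt_class}).reset_index(drop=True)


def classify_kd_effect(wt_response: pd.DataFrame, expression: pd.DataFrame,
                       sheet: pd.DataFrame,
                       attenuation_cutoff: float = DEFAULT_ATTENUATION,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Assign each gene to clusters 1-4 (or none) by KD attenuation."""
    esc = _samples(sheet, "KD", "ESC")
    npc = _samples(sheet, "KD", "NPC")
    kd_delta = _delta(expression, esc, npc, pseudocount)
    out = wt_response.copy()
    out["kd_delta"] = kd_delta.loc[out["gene_id"]].to_numpy()
    nonflat = out["wt_class"] != "flat"
    if (nonflat & (out["wt_delta"] == 0)).any():
        raise RuntimeError("non-flat gene with wt_delta == 0; inconsistent input")
    atten = np.full(len(out), np.nan)
    atten[nonflat.to_numpy()] = (
        out.loc[nonflat, "kd_delta"] / out.loc[nonflat, "wt_delta"]).to_numpy()
    out["attenuation"] = atten
    affected = atten < attenuation_cutoff
    cluster = np.full(len(out), "none", dtype=object)
    up = (out["wt_class"] == "induced").to_numpy()
    down = (out["wt_class"] == "repressed").to_numpy()
    cluster[up & ~affected] = "1"
    cluster[up & affected] = "2"
    cluster[down & ~affected] = "3"
    cluster[down & affected] = "4"
    out["cluster"] = cluster
    return out


def cluster_profiles(calls: pd.DataFrame, n_clusters: int = 4,
                     random_state: int | None = None) -> pd.DataFrame:
    """Agglomerative (Ward) clustering of non-flat (wt_delta, kd_delta)
    profiles; a cross-check for the attenuation rule, not the primary
    classifier."""
    from sklearn.cluster import AgglomerativeClustering

    nonflat = calls.loc[calls["wt_class"] != "flat"].copy()
    if len(nonflat) < n_clusters:
        raise ValueError("fewer non-flat genes than clusters")
    X = nonflat[["wt_delta", "kd_delta"]].to_numpy()
    labels = AgglomerativeClustering(n_clusters=n_clusters).fit_predict(X)
    nonflat["agglom_cluster"] = labels
    return nonflat
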