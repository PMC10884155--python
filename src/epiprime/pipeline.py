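"""End-to-end orchestration of the analysis stages on a working directory.

Stage order: simulate -> merge-peaks -> call-open -> link-genes -> abc ->
intersect-tf -> kd-classify.  Each stage reads the plain-text outputs of
its predecessors from the working directory and writes its own, so stages
can be run individually or as a gated subset.  A manifest records every
parameter and the SHA-256 checksum of every output file; reruns with the
same configuration and seed reproduce identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from epiprime import abc, consensus, io, kdresponse, linkage, openness, synth, tfbind

log = logging.getLogger("epiprime")

STAGES = ["simulate", "merge-peaks", "call-open", "link-genes", "abc",
          "intersect-tf", "kd-classify"]


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus the seed.

    ``simulate`` holds :class:`epiprime.synth.SimConfig` overrides; unknown
    keys anywhere are rejected so typos cannot silently fall back to
    defaults.
    """

    stages: list = field(default_factory=lambda: list(STAGES))
    simulate: dict = field(default_factory=dict)
    width: int = 500
    spm_cutoff: float = 2.0
    fdr: float = 0.005
    link_window: int = 5_000
    min_fc: float = 2.0
    abc_width: int = 250
    top_n: int = 150_000
    abc_threshold: float = 0.02
    abc_window: int = 5_000_000
    gamma: float = 1.0
    promoter_window: int = 2_000
    lfc: float = 1.0
    attenuation: float = 0.5
    anchor: str = "enhancer"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        sim = data.get("simulate", {})
        sim_known = {f.name for f in dataclasses.fields(synth.SimConfig)}
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulate keys: {sorted(sim_unknown)}")
        cfg = cls(**data)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def sim_config(self) -> synth.SimConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        if "genome" in params:
            params["genome"] = [(str(c), int(l)) for c, l in params["genome"]]
        return synth.SimConfig(**params)


def _data_paths(outdir: Path) -> dict[str, Path]:
    return {k: outdir / "data" / v for k, v in synth.MANIFEST.items()}


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


def _wt_samples(sheet: pd.DataFrame, stage: str) -> list[str]:
    return sheet.loc[(sheet["genotype"] == "WT") & (sheet["stage"] == stage),
                     "sample"].tolist()


# ----------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    ds = synth.simulate(cfg.sim_config())
    paths = synth.write_dataset(ds, outdir / "data")
    return list(paths.values())


def stage_merge_peaks(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    data = _data_paths(outdir)
    genome = io.read_genome(_require(data["genome"]))
    peaksets = [io.read_narrowpeak(_require(data[f"peaks_{c}"]), sample_id=c)
                for c in synth.CONDITIONS]
    cons = consensus.iterative_merge(peaksets, width=cfg.width,
                                     spm_cutoff=cfg.spm_cutoff, genome=genome)
    out = outdir / "consensus.tsv"
    io.write_table(cons[["chrom", "start", "end", "name", "spm", "strand",
                         "summit", "sample_id"]], out)
    return [out]


def stage_call_open(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    data = _data_paths(outdir)
    genome = io.read_genome(_require(data["genome"]))
    cons = io.read_table(_require(outdir / "consensus.tsv"))
    peaksets = [io.read_narrowpeak(data[f"peaks_{c}"]) for c in synth.CONDITIONS]
    frags = {c: io.read_bed3(_require(data[f"fragments_{c}"]))
             for c in synth.CONDITIONS}

    merged = openness.merge_all_peaks(peaksets)
    pseudo = {c: openness.make_pseudo_input(frags[c], merged)
              for c in synth.CONDITIONS}
    bg = openness.background_windows(genome, merged, width=cfg.width)
    pooled = np.concatenate([
        openness.normalize_rp10m(pseudo[c], bg, total_unique=len(frags[c]))
        for c in synth.CONDITIONS])
    threshold = openness.estimate_background_threshold(pooled, fdr=cfg.fdr)

    sig = {c: openness.normalize_rp10m(frags[c], cons) for c in synth.CONDITIONS}
    calls, summary = openness.classify_openness(cons, sig["A"], sig["B"],
                                                threshold)
    out_calls = outdir / "openness.tsv"
    io.write_table(calls, out_calls)
    out_summary = outdir / "openness_summary.json"
    out_summary.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return [out_calls, out_summary]


def stage_link_genes(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    data = _data_paths(outdir)
    calls = io.read_table(_require(outdir / "openness.tsv"))
    genes = io.read_genes(_require(data["genes"]))
    expr = io.read_expression(_require(data["expression"]))
    sheet = io.read_sample_sheet(_require(data["samples"]))

    links = linkage.link_peaks_to_genes(calls, genes, window=cfg.link_window)
    filtered = linkage.fold_change_filter(links, min_fc=cfg.min_fc)
    induced, missing = linkage.induction_genes(
        filtered, expr, _wt_samples(sheet, "ESC"), _wt_samples(sheet, "NPC"),
        min_lfc=cfg.lfc)
    if missing:
        log.warning("%d linked genes missing from expression matrix", len(missing))
    primed = linkage.primed_promoter_peaks(calls, induced, links)

    frac_rows = []
    for label in ("C", "I", "N"):
        sub = calls.loc[calls["label"] == label]
        frac = linkage.tss_fraction(sub, genes, window=cfg.link_window) \
            if len(sub) else float("nan")
        frac_rows.append((label, len(sub), frac))
    outs = {
        "links": outdir / "links.tsv",
        "induction": outdir / "induction_genes.tsv",
        "primed": outdir / "primed_peaks.tsv",
        "tssfrac": outdir / "tss_fractions.tsv",
    }
    io.write_table(filtered, outs["links"])
    io.write_table(pd.DataFrame({"gene_id": induced}), outs["induction"])
    io.write_table(primed, outs["primed"])
    io.write_table(pd.DataFrame(frac_rows,
                                columns=["label", "n_peaks", "tss_fraction"]),
                   outs["tssfrac"])
    return list(outs.values())


def stage_abc(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    data = _data_paths(outdir)
    genome = io.read_genome(_require(data["genome"]))
    peaks_b = io.read_narrowpeak(_require(data["peaks_B"]))
    frags_b = io.read_bed3(_require(data["fragments_B"]))
    k27_b = io.read_bed3(_require(data["k27_B"]))
    genes = io.read_genes(_require(data["genes"]))

    elements = abc.make_candidate_elements(peaks_b, frags_b, top_n=cfg.top_n,
                                           width=cfg.abc_width, genome=genome)
    model = abc.ContactModel(mode="powerlaw", gamma=cfg.gamma)
    pairs = abc.score_all_genes(elements, genes, frags_b, k27_b, model,
                                window=cfg.abc_window,
                                threshold=cfg.abc_threshold)
    bedpe = abc.pairs_to_bedpe(pairs)
    out_elems = outdir / "candidate_elements.tsv"
    out_pairs = outdir / "abc_pairs.bedpe"
    io.write_table(elements, out_elems)
    io.write_bedpe(bedpe, out_pairs)
    return [out_elems, out_pairs]


def stage_intersect_tf(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    data = _data_paths(outdir)
    chip = io.read_narrowpeak(_require(data["chip_peaks"]))
    pairs = io.read_bedpe(_require(outdir / "abc_pairs.bedpe"))
    genes = io.read_genes(_require(data["genes"]))

    bound = tfbind.intersect_pairs(chip, pairs, anchor=cfg.anchor)
    prom_bound = tfbind.promoter_binding(chip, genes,
                                         promoter_window=cfg.promoter_window)
    targets = tfbind.export_target_genes(bound, prom_bound)
    outs = {
        "bound": outdir / "bound_pairs.bedpe",
        "prom": outdir / "promoter_bound_genes.tsv",
        "targets": outdir / "target_genes.tsv",
    }
    io.write_bedpe(bound, outs["bound"])
    io.write_table(pd.DataFrame({"gene_id": prom_bound}), outs["prom"])
    io.write_table(targets, outs["targets"])
    return list(outs.values())


def stage_kd_classify(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    data = _data_paths(outdir)
    expr = io.read_expression(_require(data["expression"]))
    sheet = io.read_sample_sheet(_require(data["samples"]))
    wt = kdresponse.define_wt_response(expr, sheet, lfc_threshold=cfg.lfc)
    calls = kdresponse.classify_kd_effect(wt, expr, sheet,
                                          attenuation_cutoff=cfg.attenuation)
    out = outdir / "kd_response.tsv"
    io.write_table(calls, out)
    return [out]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "merge-peaks": stage_merge_peaks,
    "call-open": stage_call_open,
    "link-genes": stage_link_genes,
    "abc": stage_abc,
    "intersect-tf": stage_intersect_tf,
    "kd-classify": stage_kd_classify,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    from epiprime import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        outputs.extend(_STAGE_FUNCS[stage](config, outdir))
        log.info("stage %-12s %.2fs", stage, time.perf_counter() - t0)
    manifest = {
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "outputs": {str(p.relative_to(outdir)): _sha256(p)
                    for p in sorted(set(outputs))},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
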