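"""Ground-truthed two-condition multi-omic toy dataset generator.

The generator emulates the data structure of an iPSC (condition A) to NPC
(condition B) differentiation study at desk scale: planted open-chromatin
regions over a uniform fragment background, promoter-coupled expression,
enhancer-coupled H3K27ac, a neural TF binding NPC enhancers and a subset
of primed promoters, and a knockdown expression arm.

Planted region design
---------------------
* common (class C, open in both conditions): promoters of induced
  ("primed") genes, promoters of flat housekeeping genes, and a few
  common enhancers near primed genes;
* A-specific (class I): promoters of repressed stemness genes plus
  A-active enhancers targeting them;
* B-specific (class N): enhancers placed 10-60 kb from primed-gene TSSs,
  each targeting that gene;
* decoys: closed regions emitted as weak false-positive peak calls in
  both conditions, which the openness stage should leave unassigned.

Fragment counts per region and condition are negative binomial (the
standard overdispersed ATAC count model) with mean ``rate x
n_background_reads / 1e7`` -- rates are expressed per 10 million
background fragments.  A fragment belongs to a region iff its midpoint
does.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from epiprime import io, regions

FRAGMENT_HALF = 50
MIN_SEP_UNIFORM = 12_000
MIN_SEP_NEAR = 2_000
EDGE_MARGIN = 100_000
ENH_OFFSET_LO = 10_000
ENH_OFFSET_HI = 60_000
NEAR_GENE_LO = 3_000
NEAR_GENE_HI = 4_800
FAR_GENE_MIN = 20_000
KD_DEPENDENT_FRAC = 0.5
N_REPLICATES = 3

CONDITIONS = ("A", "B")


class PlacementError(RuntimeError):
    """Non-overlapping region placement failed within the attempt budget."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Rates are expected planted fragment midpoints per region per 10 million
    background fragments; with the defaults (open 10,000 / closed 100 at
    100,000 background fragments per condition over a 10 Mb genome) a
    planted open region carries ~100 planted midpoints over a ~5-midpoint
    local background, and decoys stay near background level.
    """

    genome: list = field(default_factory=lambda: [("chr1", 5_000_000),
                                                  ("chr2", 5_000_000)])
    n_common: int = 50
    n_a_specific: int = 30
    n_b_specific: int = 30
    n_closed_decoy: int = 50
    region_width: int = 500
    open_rate: float = 10_000.0
    closed_rate: float = 100.0
    dispersion: float = 20.0
    n_background_reads: int = 100_000
    n_genes: int = 200
    frac_genes_near_peak: float = 0.5
    tf_frac_enh: float = 0.6
    tf_frac_prom: float = 0.4
    gamma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not self.genome or any(l <= 0 for _, l in self.genome):
            raise ValueError("genome must have positive chromosome lengths")
        for name in ("n_common", "n_a_specific", "n_b_specific",
                     "n_closed_decoy", "n_genes", "n_background_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.region_width <= 0 or self.region_width % 2:
            raise ValueError("region_width must be positive and even")
        if self.open_rate <= self.closed_rate:
            raise ValueError("open_rate must exceed closed_rate")
        if self.closed_rate < 0 or self.dispersion <= 0:
            raise ValueError("rates must be >= 0 and dispersion > 0")
        if not 0 <= self.frac_genes_near_peak <= 1:
            raise ValueError("frac_genes_near_peak must be in [0, 1]")
        for name in ("tf_frac_enh", "tf_frac_prom"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for every planted entity.

    regions: region_id, interval, cls (C/I/N/decoy), role, gene_id, tf_bound
    genes: gene_id, cls (induced/repressed/flat), kd_dependent, primed,
           promoter_tf_bound
    enhancer_targets: region_id, gene_id, active (A/B/both)
    """

    regions: pd.DataFrame
    genes: pd.DataFrame
    enhancer_targets: pd.DataFrame


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict
    fragments: dict       # condition -> BED3 DataFrame (ATAC)
    k27_fragments: dict   # condition -> BED3 DataFrame (H3K27ac)
    peaks: dict           # condition -> narrowPeak-style DataFrame
    genes: pd.DataFrame
    expression: pd.DataFrame
    sample_sheet: pd.DataFrame
    chip_peaks: pd.DataFrame
    truth: SyntheticTruth


# ------------------------------------------------------------- placement

def _gap_conflict(placed, chrom, start, end, min_sep):
    for c, s, e in placed:
        if c == chrom and s < end + min_sep and e > start - min_sep:
            return True
    return False


def _place_uniform(rng, genome_items, placed, width, min_sep,
                   attempts=10_000):
    chroms = [c for c, _ in genome_items]
    lengths = np.array([l for _, l in genome_items], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(attempts):
        ci = rng.choice(len(chroms), p=probs)
        chrom, length = genome_items[ci]
        lo, hi = EDGE_MARGIN, length - EDGE_MARGIN - width
        if hi <= lo:
            lo, hi = 0, length - width
            if hi <= lo:
                continue
        start = int(rng.integers(lo, hi))
        if not _gap_conflict(placed, chrom, start, start + width, min_sep):
            placed.append((chrom, start, start + width))
            return chrom, start, start + width
    raise PlacementError("could not place a region without overlap; "
                         "genome too small for the requested counts")


def _place_near(rng, genome, placed, chrom, anchor, width,
                lo_off, hi_off, min_sep, attempts=2_000):
    length = genome[chrom]
    for _ in range(attempts):
        off = int(rng.integers(lo_off, hi_off + 1))
        if rng.random() < 0.5:
            off = -off
        center = anchor + off
        start = center - width // 2
        end = start + width
        if start < 0 or end > length:
            continue
        if not _gap_conflict(placed, chrom, start, end, min_sep):
            placed.append((chrom, start, end))
            return chrom, start, end
    raise PlacementError("could not place a linked region near its anchor")


def _nb_counts(rng, mean, dispersion, n):
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n).astype(np.int64)


def _uniform_fragments(rng, genome, n):
    if n == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(chroms), size=n, p=probs)
    mids = np.empty(n, dtype=np.int64)
    for i, c in enumerate(chroms):
        mask = idx == i
        if mask.any():
            mids[mask] = rng.integers(FRAGMENT_HALF,
                                      genome[c] - FRAGMENT_HALF,
                                      size=int(mask.sum()))
    return pd.DataFrame({"chrom": np.array(chroms, dtype=object)[idx],
                         "start": mids - FRAGMENT_HALF,
                         "end": mids + FRAGMENT_HALF})


def _region_fragments(rng, genome, region_rows, counts):
    chunks = []
    for (chrom, start, end), cnt in zip(region_rows, counts):
        if cnt == 0:
            continue
        mids = rng.integers(start, end, size=int(cnt))
        length = genome[chrom]
        frag_start = np.clip(mids - FRAGMENT_HALF, 0, None)
        frag_end = np.clip(mids + FRAGMENT_HALF, None, length)
        chunks.append(pd.DataFrame({"chrom": chrom, "start": frag_start,
                                    "end": frag_end}))
    if not chunks:
        return _uniform_fragments(rng, genome, 0)
    return pd.concat(chunks, ignore_index=True)


# ------------------------------------------------------------- simulate

def _open_in(cls: str, condition: str) -> bool:
    return (cls == "C") or (cls == "I" and condition == "A") \
        or (cls == "N" and condition == "B")


def simulate(config: SimConfig) -> SimulatedDataset:
    """Generate the full synthetic dataset; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = dict(config.genome)
    genome_items = list(genome.items())
    width = config.region_width

    n_primed = round(0.5 * config.n_common)
    n_flat_prom = round(0.3 * config.n_common)
    n_common_enh = config.n_common - n_primed - n_flat_prom
    n_a_prom = config.n_a_specific // 2
    n_a_enh = config.n_a_specific - n_a_prom

    placed: list = []
    region_rows = []  # (region_id, chrom, start, end, cls, role, gene_id)
    rid = 0

    def add(chrom, start, end, cls, role, gene_id=""):
        nonlocal rid
        region_rows.append([f"reg{rid:04d}", chrom, start, end, cls, role, gene_id])
        rid += 1
        return region_rows[-1]

    primed_regions = [add(*_place_uniform(rng, genome_items, placed, width,
                                          MIN_SEP_UNIFORM), "C", "promoter")
                      for _ in range(n_primed)]
    flat_regions = [add(*_place_uniform(rng, genome_items, placed, width,
                                        MIN_SEP_UNIFORM), "C", "promoter")
                    for _ in range(n_flat_prom)]
    a_prom_regions = [add(*_place_uniform(rng, genome_items, placed, width,
                                          MIN_SEP_UNIFORM), "I", "promoter")
                      for _ in range(n_a_prom)]
    for _ in range(config.n_closed_decoy):
        add(*_place_uniform(rng, genome_items, placed, width,
                            MIN_SEP_UNIFORM), "decoy", "decoy")

    def place_enhancers(n, anchors, cls):
        rows = []
        for i in range(n):
            if anchors:
                anchor = anchors[int(rng.integers(0, len(anchors)))]
                chrom = anchor[1]
                center = (anchor[2] + anchor[3]) // 2
                rows.append(add(*_place_near(rng, genome, placed, chrom, center,
                                             width, ENH_OFFSET_LO, ENH_OFFSET_HI,
                                             MIN_SEP_NEAR), cls, "enhancer"))
            else:
                rows.append(add(*_place_uniform(rng, genome_items, placed, width,
                                                MIN_SEP_UNIFORM), cls, "enhancer"))
        return rows

    common_enh = place_enhancers(n_common_enh, primed_regions, "C")
    a_enh = place_enhancers(n_a_enh, a_prom_regions, "I")
    b_enh = place_enhancers(config.n_b_specific, primed_regions, "N")

    # ------------------------------------------------------------ genes
    promoter_regions = primed_regions + flat_regions + a_prom_regions
    n_struct = len(promoter_regions)
    if config.n_genes < n_struct:
        raise ValueError(
            f"n_genes ({config.n_genes}) must cover the {n_struct} "
            "promoter-bearing planted regions")
    gene_rows = []  # gene_id, chrom, tss, strand, body_start, body_end, cls
    gid = 0

    def add_gene(chrom, tss, cls):
        nonlocal gid
        gene_id = f"gene{gid:04d}"
        gid += 1
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(5_000, 50_000))
        if strand == "+":
            body_start, body_end = tss, min(tss + length, genome[chrom])
        else:
            body_start, body_end = max(tss - length, 0), tss + 1
        gene_rows.append([gene_id, chrom, int(tss), strand,
                          int(body_start), int(body_end), cls])
        return gene_id

    gene_cls_of_role = {"primed": "induced", "flat": "flat", "a_prom": "repressed"}
    for row, role in (
        [(r, "primed") for r in primed_regions]
        + [(r, "flat") for r in flat_regions]
        + [(r, "a_prom") for r in a_prom_regions]
    ):
        center = (row[2] + row[3]) // 2
        row[6] = add_gene(row[1], center, gene_cls_of_role[role])

    n_near_target = round(config.frac_genes_near_peak * config.n_genes)
    n_extra_near = max(0, min(n_near_target, config.n_genes) - n_struct)
    all_regions = region_rows
    for _ in range(n_extra_near):
        if not all_regions:
            break
        reg = all_regions[int(rng.integers(0, len(all_regions)))]
        chrom = reg[1]
        center = (reg[2] + reg[3]) // 2
        for _ in range(200):
            off = int(rng.integers(NEAR_GENE_LO, NEAR_GENE_HI + 1))
            if rng.random() < 0.5:
                off = -off
            tss = center + off
            if 1_000 <= tss < genome[chrom] - 1_000:
                add_gene(chrom, tss, "flat")
                break

    n_far = config.n_genes - gid
    chroms = [c for c, _ in genome_items]
    lengths = np.array([l for _, l in genome_items], dtype=float)
    probs = lengths / lengths.sum()
    for _ in range(max(0, n_far)):
        for _ in range(5_000):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom, length = genome_items[ci]
            tss = int(rng.integers(1_000, length - 1_000))
            far = all(not (c == chrom and s - FAR_GENE_MIN < tss < e + FAR_GENE_MIN)
                      for c, s, e in placed)
            if far:
                add_gene(chrom, tss, "flat")
                break
        else:
            raise PlacementError("could not place a background gene away from peaks")

    genes = pd.DataFrame(
        [r[:6] for r in gene_rows],
        columns=["gene_id", "chrom", "tss", "strand", "body_start", "body_end"])
    genes = genes[io.GENE_COLS]
    gene_cls = pd.Series({r[0]: r[6] for r in gene_rows})

    # -------------------------------------------------- enhancer targets
    target_rows = []
    for row in common_enh:
        if primed_regions:
            anchor = _nearest_anchor(row, primed_regions)
            row[6] = anchor[6]
            target_rows.append((row[0], anchor[6], "both"))
    for row in a_enh:
        if a_prom_regions:
            anchor = _nearest_anchor(row, a_prom_regions)
            row[6] = anchor[6]
            target_rows.append((row[0], anchor[6], "A"))
    for row in b_enh:
        if primed_regions:
            anchor = _nearest_anchor(row, primed_regions)
            row[6] = anchor[6]
            target_rows.append((row[0], anchor[6], "B"))
    enhancer_targets = pd.DataFrame(target_rows,
                                    columns=["region_id", "gene_id", "active"])

    region_df = pd.DataFrame(region_rows,
                             columns=["region_id", "chrom", "start", "end",
                                      "cls", "role", "gene_id"])

    # ------------------------------------------------------------ TF peaks
    def pick(rows, frac):
        k = round(frac * len(rows))
        if k == 0:
            return []
        idx = rng.choice(len(rows), size=k, replace=False)
        return [rows[i] for i in sorted(idx)]

    tf_enh = pick(b_enh, config.tf_frac_enh)
    tf_prom = pick(primed_regions, config.tf_frac_prom)
    tf_bound_ids = {r[0] for r in tf_enh} | {r[0] for r in tf_prom}
    region_df["tf_bound"] = region_df["region_id"].isin(tf_bound_ids)

    chip_rows = []
    for i, row in enumerate(tf_enh + tf_prom):
        j1 = int(rng.integers(0, 101))
        j2 = int(rng.integers(0, 101))
        start = max(0, row[2] - j1)
        end = min(genome[row[1]], row[3] + j2)
        chip_rows.append((row[1], start, end, f"chip_{i}",
                          float(rng.integers(100, 1000)), ".",
                          float(rng.integers(100, 1000)), (start + end) // 2))
    chip_peaks = pd.DataFrame(chip_rows,
                              columns=["chrom", "start", "end", "name", "score",
                                       "strand", "signal", "summit"])
    if chip_peaks.empty:
        chip_peaks = chip_peaks.astype({"start": np.int64, "end": np.int64,
                                        "score": float, "signal": float,
                                        "summit": np.int64})
    chip_peaks = regions.sort_intervals(chip_peaks)

    # ------------------------------------------------------- ATAC fragments
    depth_factor = config.n_background_reads / 1e7
    region_intervals = [(r[1], r[2], r[3]) for r in region_rows]
    planted_counts = {}
    fragments = {}
    for cond in CONDITIONS:
        means = np.array([
            (config.open_rate if _open_in(r[4], cond) else config.closed_rate)
            * depth_factor
            for r in region_rows])
        counts = np.array([
            _nb_counts(rng, m, config.dispersion, 1)[0] for m in means
        ], dtype=np.int64) if len(means) else np.zeros(0, dtype=np.int64)
        planted_counts[cond] = counts
        bg = _uniform_fragments(rng, genome, config.n_background_reads)
        planted = _region_fragments(rng, genome, region_intervals, counts)
        fragments[cond] = pd.concat([bg, planted], ignore_index=True)

    # ------------------------------------------------------ H3K27ac fragments
    k27_fragments = {}
    n_k27_bg = config.n_background_reads // 2
    for cond in CONDITIONS:
        k27_counts = np.zeros(len(region_rows), dtype=np.int64)
        for i, r in enumerate(region_rows):
            if not _open_in(r[4], cond):
                continue
            base = planted_counts[cond][i]
            if r[5] == "enhancer":
                k27_counts[i] = rng.poisson(max(base, 0))
            elif r[5] == "promoter":
                k27_counts[i] = rng.poisson(0.7 * max(base, 0))
        bg = _uniform_fragments(rng, genome, n_k27_bg)
        planted = _region_fragments(rng, genome, region_intervals, k27_counts)
        k27_fragments[cond] = pd.concat([bg, planted], ignore_index=True)

    # ------------------------------------------------------------- peaks
    peaks = {}
    for cond in CONDITIONS:
        rows = []
        observed = regions.count_midpoints(
            fragments[cond],
            pd.DataFrame(region_intervals, columns=["chrom", "start", "end"]))
        for i, r in enumerate(region_rows):
            if _open_in(r[4], cond) or r[4] == "decoy":
                chrom, start, end = r[1], r[2], r[3]
                rows.append((chrom, start, end, r[0], float(observed[i]), ".",
                             float(observed[i]), (start + end) // 2, cond))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                         "score", "strand", "signal",
                                         "summit", "sample_id"])
        if df.empty:
            df = df.astype({"start": np.int64, "end": np.int64, "score": float,
                            "signal": float, "summit": np.int64})
        peaks[cond] = regions.sort_intervals(df)

    # --------------------------------------------------------- expression
    n_genes = len(genes)
    base = 2.0 ** rng.normal(5.0, 1.0, n_genes)
    cls_arr = gene_cls.loc[genes["gene_id"]].to_numpy()
    lfc = np.zeros(n_genes)
    induced_mask = cls_arr == "induced"
    repressed_mask = cls_arr == "repressed"
    lfc[induced_mask] = rng.uniform(1.0, 3.0, int(induced_mask.sum()))
    lfc[repressed_mask] = -rng.uniform(1.0, 3.0, int(repressed_mask.sum()))

    nonflat = induced_mask | repressed_mask
    kd_dependent = np.zeros(n_genes, dtype=bool)
    nonflat_idx = np.flatnonzero(nonflat)
    if len(nonflat_idx):
        k = round(KD_DEPENDENT_FRAC * len(nonflat_idx))
        chosen = rng.choice(nonflat_idx, size=k, replace=False)
        kd_dependent[np.sort(chosen)] = True
    r_true = np.ones(n_genes)
    r_true[nonflat & kd_dependent] = rng.uniform(
        0.0, 0.3, int((nonflat & kd_dependent).sum()))
    r_true[nonflat & ~kd_dependent] = rng.uniform(
        0.8, 1.1, int((nonflat & ~kd_dependent).sum()))

    group_means = {
        ("WT", "ESC"): base,
        ("WT", "NPC"): base * 2.0 ** lfc,
        ("KD", "ESC"): base,
        ("KD", "NPC"): base * 2.0 ** (lfc * r_true),
    }
    samples, sheet_rows, columns = [], [], {}
    for genotype in ("WT", "KD"):
        for stage in ("ESC", "NPC"):
            for rep in range(1, N_REPLICATES + 1):
                name = f"{genotype}_{stage}_{rep}"
                noise = 2.0 ** rng.normal(0.0, 0.2, n_genes)
                columns[name] = group_means[(genotype, stage)] * noise
                sheet_rows.append((name, genotype, stage))
    expression = pd.DataFrame(columns, index=pd.Index(genes["gene_id"],
                                                      name="gene_id"))
    sample_sheet = pd.DataFrame(sheet_rows,
                                columns=["sample", "genotype", "stage"])

    truth_genes = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "cls": cls_arr,
        "kd_dependent": kd_dependent,
        "primed": induced_mask,
        "promoter_tf_bound": genes["gene_id"].isin(
            {r[6] for r in tf_prom}).to_numpy(),
    }).reset_index(drop=True)

    truth = SyntheticTruth(regions=region_df, genes=truth_genes,
                           enhancer_targets=enhancer_targets)
    return SimulatedDataset(config=config, genome=genome, fragments=fragments,
                            k27_fragments=k27_fragments, peaks=peaks,
                            genes=genes, expression=expression,
                            sample_sheet=sample_sheet, chip_peaks=chip_peaks,
                            truth=truth)


def _nearest_anchor(row, anchors):
    """Anchor region nearest to ``row`` on the same chromosome."""
    center = (row[2] + row[3]) // 2
    same = [a for a in anchors if a[1] == row[1]]
    pool = same if same else anchors
    return min(pool, key=lambda a: abs((a[2] + a[3]) // 2 - center))


# ------------------------------------------------------------- round trip

MANIFEST = {
    "genome": "genome.tsv",
    "fragments_A": "atac_fragments_A.bed",
    "fragments_B": "atac_fragments_B.bed",
    "k27_A": "k27_fragments_A.bed",
    "k27_B": "k27_fragments_B.bed",
    "peaks_A": "peaks_A.narrowPeak",
    "peaks_B": "peaks_B.narrowPeak",
    "genes": "genes.tsv",
    "expression": "expression.tsv",
    "samples": "samples.tsv",
    "chip_peaks": "chip_peaks.narrowPeak",
    "truth_regions": "truth_regions.tsv",
    "truth_genes": "truth_genes.tsv",
    "truth_enhancers": "truth_enhancers.tsv",
}


def write_dataset(dataset: SimulatedDataset, directory) -> dict[str, Path]:
    """Write every component as plain text; returns the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in MANIFEST.items()}
    io.write_genome(dataset.genome, paths["genome"])
    for cond in CONDITIONS:
        io.write_bed3(dataset.fragments[cond], paths[f"fragments_{cond}"])
        io.write_bed3(dataset.k27_fragments[cond], paths[f"k27_{cond}"])
        io.write_narrowpeak(dataset.peaks[cond], paths[f"peaks_{cond}"])
    io.write_genes(dataset.genes, paths["genes"])
    io.write_expression(dataset.expression, paths["expression"])
    io.write_sample_sheet(dataset.sample_sheet, paths["samples"])
    io.write_narrowpeak(dataset.chip_peaks, paths["chip_peaks"])
    io.write_table(dataset.truth.regions, paths["truth_regions"])
    io.write_table(dataset.truth.genes, paths["truth_genes"])
    io.write_table(dataset.truth.enhancer_targets, paths["truth_enhancers"])
    return paths


def read_dataset(directory) -> SimulatedDataset:
    """Read a written dataset back; inverse of :func:`write_dataset`."""
    directory = Path(directory)
    paths = {k: directory / v for k, v in MANIFEST.items()}
    genome = io.read_genome(paths["genome"])
    fragments = {c: io.read_bed3(paths[f"fragments_{c}"]) for c in CONDITIONS}
    k27 = {c: io.read_bed3(paths[f"k27_{c}"]) for c in CONDITIONS}
    peaks = {c: io.read_narrowpeak(paths[f"peaks_{c}"], sample_id=c)
             for c in CONDITIONS}
    genes = io.read_genes(paths["genes"])
    expression = io.read_expression(paths["expression"])
    sheet = io.read_sample_sheet(paths["samples"])
    chip = io.read_narrowpeak(paths["chip_peaks"])
    truth = SyntheticTruth(
        regions=io.read_table(paths["truth_regions"]),
        genes=io.read_table(paths["truth_genes"]),
        enhancer_targets=io.read_table(paths["truth_enhancers"]),
    )
    return SimulatedDataset(config=None, genome=genome, fragments=fragments,
                            k27_fragments=k27, peaks=peaks, genes=genes,
                            expression=expression, sample_sheet=sheet,
                            chip_peaks=chip, truth=truth)
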