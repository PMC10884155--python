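# Methods

`epiprime` re-implements, as a tested library, the epigenome-integration
computations used to dissect chromatin openness during iPSC-to-NPC neural
differentiation: which regions are open in which state, which genes they
serve, which enhancers drive which promoters, and which genes fail to
respond when the driving transcription factor is knocked down.  This note
describes each model, its assumptions, the tunable parameters, and the
choices made where the design was genuinely open.

Throughout, condition A plays the stem-cell (iPSC/ESC) state and
condition B the neural-progenitor (NPC) state.  All coordinates are
0-based half-open; two intervals overlap iff they share at least one base
pair; a fragment "is in" a region iff its midpoint is (the unambiguous
reading of shifted-cut-site ATAC counting).

## Consensus peak construction

Per-sample peak scores are first normalized to score-per-million,
`spm_i = score_i * 1e6 / sum_j score_j`, so samples of different depth are
comparable.  Peaks are resized to a fixed width (default 500 bp) around
their summits, clipped at chromosome bounds (clipped peaks flagged but
kept — they still carry signal), pooled, and ranked by spm.  The ranked
list is scanned greedily: the top peak is retained, every remaining peak
overlapping it is discarded, and so on; retained peaks with spm below the
cutoff (default 2) are then removed.  Equal-spm ties break toward the
smaller (chrom, start), so the result is deterministic.  Whether the spm
cutoff precedes or follows overlap removal is not fixed by the procedure's
usual description; we apply it after removal, which is the more permissive
reading (a low-spm peak can still shadow a lower one), and the cutoff is a
parameter so the alternative is one call away.

## Openness classification against a pseudo-input background

Differential-accessibility testing cannot distinguish "open in both" from
"closed in both".  The peak-recall procedure instead dichotomizes: all
called peaks from both conditions are merged into a foreground set;
fragments overlapping the foreground are discarded, leaving a pseudo-input
that samples the genomic background; background regions are scored in both
conditions in RP10M units (midpoint count x 1e7 / total unique fragments);
and the openness threshold is the empirical (1 - FDR) quantile of the
pooled background distribution, default FDR 0.5%.

Two numerical choices matter here.  First, the quantile is the explicit
order statistic `sorted[ceil((1 - fdr) * n)]` (1-based), i.e. the "higher"
interpolation, so the achieved fraction of background values strictly
above the threshold never exceeds the nominal FDR (1,000 values 1..1000 at
FDR 0.5% give exactly 995, with 0.5% above).  Second, "open" means
strictly greater than the threshold, which keeps the all-zero degenerate
case closed.  Peaks open in both conditions are labelled C, open only in A
labelled I, only in B labelled N, neither unassigned; the four labels
partition the consensus set exactly.

The background distribution is pooled across both conditions so a single
threshold emerges (per-condition thresholds are available by calling the
estimator per condition).  On data where the pseudo-input is close to
uniform, a significance-based caller reports no background peaks at all —
correctly, since there is nothing locally enriched.  Background regions
are therefore taken as fixed-width tiling windows of the genome disjoint
from the foreground, which measures the same background signal
distribution without requiring local enrichment.  The bundled
sliding-window Poisson caller (`call_peaks_simple`, window 300 bp, step
150 bp, Benjamini-Hochberg at q = 0.05 across windows) remains available
wherever a foreground caller is needed; its defaults are module constants.

## Peak-gene linkage, induction genes, primed promoters

A peak links to a gene when the TSS lies within ±5 kb of the peak
interval, measured TSS-to-interval (0 inside) and strand-ignored.
Cluster I/N links must additionally pass a two-fold pseudocounted signal
ratio in the cluster's direction ((signal + 1) ratios, avoiding division
by zero); Cluster C links are exempt, since common peaks by construction
show no directional change.  Induction genes are Cluster-C-linked genes
with `log2((mean TPM_B + 1) / (mean TPM_A + 1)) >= 1`; the threshold is
configurable and anchored to the conventional DEG cutoff of one log2 unit.
Primed promoter peaks are Cluster C peaks whose *nearest* linked gene is
an induction gene — regions already open in the stem state whose gene
fires on differentiation; distance ties consult every tied gene rather
than dropping one arbitrarily.  The TSS-proximity statistic is the
fraction of a peak set within ±5 kb of any TSS.

## Activity-by-Contact scoring

Candidate elements are 250 bp summit-centered windows ranked by ATAC
midpoint count; the top 150,000 are kept (at desk scale, all of them),
blacklist overlaps removed, and overlapping elements merged.  Merged spans
are re-counted over the combined interval rather than summing member
counts, so a fragment shared by two members is counted once.  Activity is
the geometric mean `A = sqrt(atac x k27ac)`; contact is a power law
`C(d) = (d + d0)^(-gamma)` with gamma = 1.0 and d0 = 5 kb — the standard
fallback when no contact map is available — or a binned contact table
(uniformly spaced bins; distances beyond the table are an error; contact
must be non-increasing).  For gene g and element e within ±5 Mb of the
TSS,

    ABC(e, g) = A_e C_e / sum_{e'} A_{e'} C_{e'},

so per-gene scores sum to one and are invariant under rescaling all
activities.  Each gene's promoter element (TSS ± 250 bp) joins the
denominator; candidate elements overlapping a promoter element are
replaced by the canonical promoter element, and promoter elements are
never emitted as enhancer-gene pairs, keeping target-gene lists free of
promoter self-links.  Pairs with score >= 0.02 are reported as 10-column
BEDPE (anchor1 = element, anchor2 = promoter).

## TF-bound pairs and knockdown response

A BEDPE pair is TF-bound when a ChIP peak overlaps its enhancer anchor by
>= 1 bp (binding at the enhancer is the defining event; an "either-anchor"
mode is provided and is a superset).  Direct promoter binding uses a
±2 kb promoter window, configurable because promoter extents in browser
figures are not a programmatic definition.  Target-gene lists are
deduplicated with evidence class enhancer / promoter / both.

For the knockdown arm, the wild-type response per gene is
`wt_delta = log2((mean TPM_NPC + 1) / (mean TPM_ESC + 1))`; induced means
>= 1, repressed <= -1, else flat.  The knockdown attenuation
`r = kd_delta / wt_delta` measures the fraction of the wild-type
log-change the KD line achieves; `r < 0.5` marks the gene "affected".
Clusters: 1 = up/unaffected, 2 = up/affected, 3 = down/unaffected,
4 = down/affected; flat genes are outside the partition.  The original
analysis assigned clusters by hierarchical clustering of expression
profiles with unstated metric, linkage and k; the attenuation rule is an
explicit, deterministic formulation of the same dichotomy, and Ward
clustering of the (wt_delta, kd_delta) profiles is retained as an optional
cross-check (`kdresponse.cluster_profiles`).

## The synthetic study

The generator (`epiprime.synth`) plants a two-condition design with full
ground truth: 50 common regions (half promoters of induced "primed" genes,
a third promoters of flat housekeeping genes, the rest common enhancers),
30 A-specific regions (stemness promoters and their enhancers), 30
B-specific enhancers placed 10-60 kb from primed-gene TSSs and coupled to
them, and 50 closed decoys that are nonetheless emitted as weak peak calls
in both conditions — exactly the false positives the openness stage should
leave unassigned.  Region counts per condition are negative binomial
(dispersion 20) with mean `rate x n_background / 1e7`: open rate 10,000
and closed rate 100 per 10 million background fragments, over 100,000
uniform background fragments per condition on a 2 x 5 Mb genome.  These
defaults put ~100 planted midpoints on an open region against a ~5-midpoint
local background, a separation chosen so that planted-open and decoy
regions differ by an order of magnitude in observed counts, as real peaks
do.  H3K27ac fragments are Poisson-coupled to the realized ATAC counts at
active enhancers (factor 1) and promoters (factor 0.7) over a half-depth
uniform background.  Expression uses base TPM `2^N(5, 1)`, induced log2
fold-changes Uniform(1, 3) (anchored to the one-log2-unit DEG convention),
three replicates per genotype x stage with 2^N(0, 0.2) multiplicative
noise; half the non-flat genes are planted KD-dependent with true
attenuation Uniform(0, 0.3) versus Uniform(0.8, 1.1) for independent
genes.  The TF binds 60% of B-specific enhancers and 40% of primed
promoters, with ±100 bp peak jitter.

Induced genes are planted with promoters in *common* regions — the primed
design the analysis is about; a gene whose promoter opened only in B would
also be induced, but the default design contains none, so induction-gene
recovery is measured against the planted induced set directly.

What the generator does not emulate: read-level sequence (no FASTQ), Tn5
insertion bias, fragment-length structure, copy-number or mappability
artifacts, chromatin domains beyond the power-law decay, and
peak-caller-specific scoring.  Passing tests therefore demonstrate that
the *computations* are correct and well-calibrated on data matching their
assumptions, not that the defaults are optimal for any particular real
dataset.

## Problem sizes and determinism

The bundled study (160 planted regions, 200 genes, ~216k ATAC and ~108k
H3K27ac fragments per condition) runs end to end in a few seconds; oracle
equivalence checks use 100 random instances of up to 200 peaks and
1,000+ random peak-gene pairs.  A single integer seed threads through
every random draw (numpy `default_rng`), and a repeated run with the same
configuration reproduces byte-identical outputs; the run manifest records
every parameter and output checksum.

## Known limitations

* The simplified Poisson caller has no local background model (no lambda
  tracking), so broad enrichment over a sloping background would be
  mis-called on real data.
* The power-law contact model ignores TADs, loops and the diagonal
  normalization of real contact maps; table mode accepts pre-normalized
  contact values but performs no matrix balancing.
* Openness labels depend on a single pooled threshold; condition-specific
  depth pathologies (one severely undersequenced sample) would bias labels
  toward the deeper condition.
* The attenuation rule treats r as a point estimate; it does not model
  replicate variance, so genes with wt_delta near the threshold can
  flicker between flat and cluster membership under resampling.
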