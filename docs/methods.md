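# Methods

This note records the models behind each stage, the defaults that matter and
why, what the synthetic generators do and do not emulate, and the numerical
choices a maintainer would want spelled out.

## Species demultiplexing

Each cell's human-transcript ratio is r = (UMIs on human-tagged features) /
(total UMIs), computed after cell-level QC. Species are assigned by two
thresholds, mouse at r ≤ 0.2 and human at r ≥ 0.8, with the band in between
labeled `unknown`. Both thresholds are closed: the thresholds themselves are
conventionally quoted to one decimal and a deterministic boundary rule beats
an unstated one. The ratio is over UMIs, not distinct genes ("transcripts"
read literally); a per-gene variant is available via `per_gene=True`.

QC defaults are min_genes = 200 and min_umis = 500 per cell — a conventional
droplet-data floor, fully configurable, applied before ratio computation so
empty cells never produce divide-by-zero ratios. Mitochondrial-content
filtering is deliberately not built in; it is orthogonal to species calling.
Unknown cells are not dropped by the library: callers subset on the call
table, so retaining them for diagnosis costs nothing.

Bimodality diagnosis histograms r into 50 bins over [0, 1], smooths with a
3-bin moving average (edge bins use the 2-bin window so boundary peaks are
not displaced), takes local maxima as peaks, and flags bimodality iff two
peaks are separated by a trough strictly below both. This is a diagnostic,
not a classifier; the thresholds stay fixed regardless.

## Pseudo-bulk, PCA, distances, reference mapping

Pseudo-bulk sums raw counts per sample and then normalizes to CPM before
log2(x+1) — summing first is depth-robust, the standard pseudo-bulk
practice, rather than averaging per-cell-normalized values. PCA is a
centered SVD over samples; variance fractions are relative to the total
gene-wise variance, so they are non-increasing and sum to ≤ 1. Transcriptome
distance is 1 − Pearson r between log profiles with average-linkage
clustering: scale-free, and it matches the correlation-heatmap style of
sample-similarity figures. All genes enter PCA by default; `top_k_variable`
restricts reference mapping to the panel's most variable genes when a panel
is informative only on part of the transcriptome.

Reference mapping is Spearman rank correlation of each sample against each
panel column on shared genes (≥ 50 required by default), best match =
row-wise argmax. Rank correlation makes the mapping invariant to monotone
per-sample transforms, so query and panel need not share a normalization.

## Differential expression

Values are log1p of counts scaled to 10⁴ per cell. The test is a two-sided
Wilcoxon rank-sum per gene — the default choice of the single-cell ecosystem
— implemented in-house so both code paths are testable:

* **Exact path** (both groups ≤ 10 cells): a shift-algorithm DP over doubled
  midranks counts, with exact integer arithmetic, the number of group-A
  assignments at every rank-sum; the two-sided p is
  P(|W − μ| ≥ |w_obs − μ|) under that permutation null. This is the tail the
  normal path's |z| approximates, and it yields p = 1 for identical groups.
* **Normal path**: tie-corrected variance with a 0.5 continuity correction.
  On tie-free data at group sizes as small as 5–8 it tracks the exact tail
  within ~0.02. With heavy ties at such sizes the rank-sum lattice becomes
  too coarse for any Gaussian approximation (steps of several midranks);
  those cases are exactly the ones the exact path covers.

log₂FC = log₂((mean_A + 1)/(mean_B + 1)) over de-logged normalized group
means; the +1 pseudocount (on the 10⁴ scale) bounds the statistic when one
group is silent. PCT is the nonzero fraction per group; the filter applies
max(pct1, pct2) > 0.1 by default (`pct_mode` switches to min), together with
BH-adjusted p < 0.05 and |log₂FC| > 0.25 — the absolute value, since
direction-specific lists can be taken downstream by sign. BH is the step-up
formula with cumulative-minimum monotonicity enforcement, returned in input
order.

## Concordance statistics

Quadrant analysis classifies genes by the signs of (fc_x, fc_y); genes with
either coordinate exactly 0 go to an explicit `axis` category rather than
being tie-broken into a quadrant. The gene universe defaults to the union of
the two comparisons' passing DEGs (genes significant in either comparison,
matching how cross-comparison scatterplots are usually drawn);
`intersection` and `all` are options. The correlation is Pearson on log₂FC
("linear" concordance), Spearman available.

The alignment score is the unnormalized sum of log₂FC over a gene set, per
its definition; `per_gene_mean=True` divides by the genes used when sets of
different sizes must be compared. Missing genes are counted and reported,
never silently imputed.

ORA is the upper-tail hypergeometric probability P(X ≥ k) with K clipped to
the universe, BH across the collection. Queries must be subsets of the
universe — a mismatch is an error rather than a silent intersection, because
it usually signals mismatched gene-ID conventions.

## Morphometry

Skeletons are rooted trees in SWC convention; the single root is the soma.
Sholl profiles count, for each sphere of radius r (step 5 µm by default)
centered on the soma, the exact number of times each parent–child segment
crosses the sphere. Distance to a fixed point is convex along a segment, so
a segment crosses 0, 1 (endpoints on opposite sides) or 2 times (both
endpoints outside, interior dip inside); touching without crossing counts 0.
This is the geometrically exact crossing count and agrees with a
dense-sampling sign-change oracle. Sholl is 3D by default; `project_xy`
flattens to the xy-plane for comparison with projected-image analyses.

Branch statistics: total length = Σ parent–child Euclidean distances,
primaries = soma's direct children, terminals = non-root leaves, effective
soma area = π r² of the soma node radius — the only soma-size datum a
skeleton carries.

Colocalization discretizes segments into ≤ 0.5 µm pieces; a piece is
colocalized iff its midpoint is within ε (default 1 µm) of any evidence
point (KD-tree query), and proximal iff its midpoint is within 40 µm
Euclidean distance of the soma center — straight-line distance, not path
distance, since the split is defined from the cell body's center. Fractions
are colocalized length over compartment length; halving the discretization
step moves results by well under 1%.

## Calcium traces

F0 is the mean fluorescence over all samples strictly before the stimulus
(the full visible baseline; at least two samples required), and
ΔF/F0 = F/F0 − 1, invariant to global scaling of F. A cell responds when
some post-stimulus sample exceeds θ = 0.10 strictly; response time is from
stimulus to the first such sample. No debouncing by default — the criterion
names no persistence requirement — but `min_consecutive` suppresses
single-sample artifacts when recordings are noisy. Group activation is the
fold change of group-mean maximum amplitude versus control; maximum
amplitude (not area under the curve, which is available as an easy
extension) matches how per-cell amplitudes are usually reported. Correlation
clustering is average linkage on 1 − Pearson r of ΔF/F0 series.

## Synthetic generators

All generators are deterministic given (config, seed) and return ground
truth sufficient to score downstream stages.

* **Barnyard droplets.** Species expression profiles are Dirichlet(0.5)
  draws over each genome's genes; per-cell depth is Poisson (floored at 1).
  Ambient contamination *replaces* a Binomial(depth, ambient_fraction) share
  of a cell's UMIs with draws from the pooled ambient profile, keeping depth
  fixed — so E[mouse-cell human ratio] = ambient_fraction × pool human share
  in closed form. Doublets are 50/50 species mixtures, the worst case for
  ratio thresholds. Defaults (5,000 UMIs/cell, 1% ambient) are fixture
  choices for a plausible droplet run, not estimates of any particular
  experiment.
* **Grouped counts.** Negative binomial with shared dispersion
  (var = μ + αμ², α = 0.5) across the five groups D0, PFC_2MPT, PFC_4MPT,
  HIP_2MPT, HIP_4MPT. Region effects split symmetrically (±effect/2 in log2)
  between PFC and HIP groups so the planted log₂FC is the PFC/HIP contrast;
  time effects scale with months/4, a monotone maturation gradient. Baseline
  means are lognormal around 5 UMIs/cell — moderately expressed genes, the
  population real DEG lists are drawn from — over a background of 1,000 null
  genes, large enough that a planted program is a small fraction of library
  depth. With few background genes, CPM normalization converts a planted
  program into a systematic apparent shift of every null gene
  (library-composition artifact); real transcriptomes are ~10× wider still,
  so the residual composition effect here is conservative.
* **Reference panels** are lognormal profiles; queries are a panel column
  plus Gaussian noise, so zero noise forces ρ = 1 best matches.
* **Skeletons** grow n_primary branches that bifurcate at each level;
  depth 1 is an unbranched segment, giving 2^(depth−1) tips per primary.
  Truth accumulates edge lengths during construction, independently of the
  morphometry module.
* **Traces** are baseline → linear ramp → plateau with Gaussian noise;
  rise_time = 0 gives a step. The planted crossing sample is therefore
  closed-form.
* **Neurite points** cover a chosen fraction of skeleton length (random
  edge order, last edge partial) at 0.2 µm spacing with an optional radial
  offset; truth is the exactly covered fraction.

What the generators do **not** emulate: gene–gene correlation structure,
cell-type heterogeneity within a sample, batch effects, ambient profiles
that differ from the cell pool, non-monotone calcium kinetics (decay,
oscillation), and imaging noise that is not additive Gaussian. Passing tests
therefore demonstrate correctness of the computations under the stated
noise models, not robustness to every artifact of real data.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run everything at desk scale:
2,000-cell demultiplexing runs, 100 cells/group × ~1,030 genes for DEG
recovery (5 seeds), 100 replicates of the alignment-score sign check at 50
cells/group, 50 skeletons against the dense Sholl oracle (0.01 µm
sampling), 1,000-draw ORA null calibration. These sizes give Monte-Carlo
error comfortably inside every asserted margin. All randomness flows from
explicit seeds; the acceptance script derives per-stage seeds from its
`--seed` argument.

## Known limitations

* The Wilcoxon engine is per-gene and ignores pseudoreplication (cells
  within an animal are treated as independent); no covariate adjustment.
* Ambient RNA is diagnosed (bimodality, unknown band) but not corrected.
* ORA treats gene sets as flat lists; no ontology graph, no GSEA.
* Effective soma area assumes a circular soma cross-section.
* Colocalization measures proximity of evidence points to the skeleton, a
  resolution-controlled surrogate for voxel-level overlap of two stains.
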