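# Methods

`csvdnet` implements a desk-scale re-analysis pipeline for the question
of how cerebral small vessel disease (CSVD) relates to the global
topology of weighted structural brain connectomes. This note documents
the models, the numerical choices, and what the synthetic validation
cohort does and does not establish.

## Graph model and global parameters

A connectome is a symmetric, non-negative weight matrix over N labelled
grey-matter regions (84 in the default configuration, matching a
Desikan-Killiany-plus-subcortical parcellation; any N ≥ 2 is
supported). Weights are dimensionless streamline strengths; the
diagonal is zero, and asymmetry beyond 1e-9 is rejected rather than
silently repaired.

**Edge lengths.** All path-based measures convert strengths to lengths
as `length = 1/weight`. With raw weights as lengths, stronger
connections would be topologically *farther*, inverting the biology;
the reciprocal is the standard convention of the major connectivity
toolboxes. This choice is deliberately documented because the
"total weight of a path" phrasing common in the literature is ambiguous
for strength-weighted graphs.

**Global efficiency** is the mean of `1/d_ij` over ordered pairs, with
disconnected pairs contributing 0, so it is defined for any graph.
Efficiency is scale-covariant; the per-subject record therefore reports
it after dividing the matrix by its maximum, which makes all reported
metrics scale-free and comparable across subjects. The normalisation
ratios (below) are unaffected, because null models share the source's
weight multiset and hence its maximum.

**Clustering** is the mean Onnela coefficient: per node, the normalised
sum of geometrically averaged triangle weights after max-scaling,
`C_i = (2/(k_i(k_i-1))) Σ (ŵ_ij ŵ_ih ŵ_jh)^(1/3)`, degree-<2 nodes
contributing 0. It is exactly invariant under global weight rescaling
and node relabeling (property-tested).

**Modularity Q** uses the weighted Newman formulation at resolution 1,
maximised by recursive spectral bisection on the generalised modularity
matrix with Kernighan–Lin single-node fine-tuning; recursion stops when
no split increases Q. The fine-tuning pass is capped at 50 sweeps and
re-scores candidates exactly at each sweep boundary, since incremental
gain accounting accumulates float drift. Tie-breaks follow a seeded
permutation, so results are bit-reproducible given the seed. On small
graphs the returned Q never exceeds the exhaustive-partition optimum,
and on the two-equal-cliques family it attains it exactly (Q = 0.5).

**Null-model normalisation.** Efficiency and clustering are divided by
their means over an ensemble (default 100, study convention) of
degree-preserving Maslov–Sneppen rewired nulls: double-edge swaps whose
weights travel with the edges, so both the binary degree sequence and
the weight multiset are preserved exactly — both are asserted, not
assumed, in the test suite. Ten attempted swaps per edge is the
standard mixing heuristic; on dense graphs most attempts are rejected
(both endpoints' replacement slots are usually occupied), which is the
scheme's expected behaviour. The ratio convention (observed / null
mean) rather than a z-score is used so that values straddle 1: dense
spatially-embedded networks show normalised efficiency below 1 and
normalised clustering above 1. The ensemble standard error (sample SD /
√n_nulls) is reported per metric. The swap kernel is JIT-compiled
(numba) because cohort-scale normalisation executes ~10⁷ swap attempts.

**Small-world propensity** locates a network between a weighted
ring-lattice null (edges placed on the smallest ring distances, the
largest weights on the shortest distances — the construction of the
small-world-propensity literature) and a degree-preserving random null:

    ΔC = (C_latt − C_obs)/(C_latt − C_rand),
    ΔL = (L_obs − L_rand)/(L_latt − L_rand),
    φ = 1 − sqrt((ΔC² + ΔL²)/2),

with both deviations clipped to [0, 1], so φ ∈ [0, 1] by construction;
φ > 0.6 is the conventional threshold for pronounced small-world
structure. L is the mean shortest path over connected ordered pairs;
disconnected inputs are reduced to their largest component (logged).
If a null pair degenerates (C_latt = C_rand, which genuinely happens
for dense unit-weight graphs where both nulls have identical
distance-1/distance-2 structure), the affected deviation is set to 0
with a warning — the observed graph is then indistinguishable from
both nulls on that axis. One lattice and one random null are used per
evaluation; the residual null-sampling noise is part of the reported
value.

## CSVD markers

**PSMD** is the 95th minus 5th percentile of mean-diffusivity values on
the white-matter skeleton, with linearly interpolated percentiles (the
default of the reference histogram-analysis script). It is
translation-invariant and scales linearly with the values; for
normal-distributed MD it equals `2 × 1.6449 × σ`, the check used in the
acceptance suite. Upstream skeletonisation (TBSS) and FA masking are
assumed done; the package consumes either NIfTI map+mask pairs or plain
value vectors.

**WMH classification.** Lesion voxels within 10 mm Euclidean distance
of the ventricles are periventricular, beyond 10 mm deep. The distance
is an exact Euclidean distance transform from ventricle voxel centres
with anisotropic voxel dimensions respected; the boundary is inclusive
(≤ 10 mm → periventricular) with a 1e-9 slack so float noise cannot
flip boundary voxels. Sub-voxel surface geometry is not modelled. The
implementation is verified voxel-exact against a brute-force pairwise
minimum-distance oracle on random volumes.

**Loads.** `load = 100 × volume / (ICV − ventricle volume)` in percent,
log10-transformed for analysis (the distribution is right-skewed; the
base only rescales regression coefficients and leaves correlations and
p-values unchanged). Zero-lesion subjects have no log; their load is
floored at half the single-voxel load before the log, keeping them in
the regression sample at the bottom of the scale rather than dropping
them — a warning marks each occurrence.

## Statistics

Associations are reported the way epidemiological cohort papers report
them: simple OLS of each graph parameter on each marker first (with
Pearson r, whose square equals the simple-model R²), then the same
model adjusted for age, sex, brain volume, median edge weight, and —
when the columns are present — smoking, hypertension, diabetes and BMI.
Rank-deficient designs are rejected with the collinear columns named.
Rows with missing values are dropped listwise per model, with counts
logged.

Correlations of one graph parameter with periventricular vs deep WMH
load are dependent (they share the parameter and are measured on the
same subjects); they are compared with the Pearson–Filon z statistic
for overlapping correlations,

    z = (r_jk − r_jh)·√n / sqrt((1−r_jk²)² + (1−r_jh²)² − 2k),
    k = r_kh(1−r_jk²−r_jh²) − ½ r_jk r_jh (1−r_jk²−r_jh²−r_kh²).

The implementation is validated two ways: its type-I error is
calibrated within [0.04, 0.06] at α = 0.05 over 10,000 trivariate-null
simulations, and its variance estimate matches a 2,000-resample
nonparametric bootstrap within 15%.

Cognitive outcomes (MMST, TMT-A, TMT-B) are modelled against seven
predictors (PSMD, periventricular and deep log-load, and the four graph
parameters), simple and adjusted for age, sex and education years.
Multiple testing is corrected per outcome across those seven tests;
Bonferroni is the default (the conservative choice when the original
method is unnamed) with Benjamini–Hochberg available.

## Synthetic cohort

No subject data accompany the study this pipeline targets, so
validation uses a generator that emulates the assumed *mechanism*, not
the observed correlations — the sign structure of the results is an
emergent property, which is what makes it worth testing.

Per cohort, 84 region centres are placed in a brain-sized ellipsoid
with a medial ventricle locus; per subject, edge weights follow
`s·exp(−d/λ)·ε` (λ = 30 mm, mean-one lognormal ε with σ = 0.5),
thresholded to a target density of 0.88 (±0.012 between subjects) —
chosen to land in the regime of dense streamline-weighted connectomes
with median edge weight near 28 and median density near 0.88. A latent
burden variable is lognormal with an age trend (median 1 at age 60,
slope 0.055/yr on the log scale, σ = 0.45; ages uniform 45–74).
Burden attenuates each edge by `exp(−burden·β·g_ij)` with β = 2.5 and
`g_ij = (d_ij/d_max)·[(1−π) + π·exp(−v_ij/25 mm)]`, where v_ij is the
edge midpoint's distance to the ventricle locus and π = 0.95: damage
concentrates on long-range tracts passing near the ventricles. These
degradation parameters were chosen so that all four global parameters
respond monotonically to burden with a small-world-propensity range
comparable to a realistic inter-subject spread; weight heterogeneity
(σ = 0.5, λ = 30 mm) matters here, because nearly homogeneous dense
graphs leave the lattice/random nulls too close together for φ to
resolve topological change.

Markers: MD values are Normal(7.4e-4, 6e-5 + 2.5e-5·burden) mm²/s
truncated positive (so PSMD at zero burden is ≈ 2.0e-4 mm²/s, rising
with burden); WMH volumes have a periventricular component
(0.8 × 0.65 mL per unit burden, lognormal noise σ = 0.25) and a deep
component (0.2 × 0.65 mL, σ = 0.75) — the deep component is noisier
because deep lesions are the more idiosyncratic compartment, and this
is what makes the periventricular load the tighter correlate of the
network damage, reproducing the periventricular-dominance comparison.
Noise factors are mean-one, so regressing generated volume on burden
recovers the configured coefficient (property-tested within 15%).
Lesions are rendered as voxels inside/beyond the 10 mm shell around a
miniature central ventricle in a 48³, 1 mm isotropic volume, so the
production classifier runs on real masks, not shortcuts. Cognition
links to the subject's *computed* network efficiency (plus age and
education effects), giving the cognitive regressions a realistic
mediation structure instead of a direct burden link.

What the generator does **not** emulate: tractography artefacts and
SIFT2 weight biases, scanner noise, spatially realistic lesion shapes,
FreeSurfer region geometry, risk-factor covariates, and the magnitude
of the real cohort's correlations. Passing tests therefore show that
the pipeline's measurements respond correctly to a known mechanism of
the assumed kind — not that the real-data effect sizes would be
reproduced.

## Problem sizes and determinism

The validation cohort uses 200 subjects with 20 nulls per subject
(≈ 2–3 minutes end to end on one core); the production default remains
100 nulls. All randomness flows from a single integer seed through
`numpy` SeedSequence spawning: cohorts, per-subject noise, rewiring
ensembles (member k seeded `seed + k`) and tie-breaks are
bit-reproducible, which the test suite asserts at table level.

## Known limitations

* Spectral bisection with fine-tuning is a strong heuristic, not an
  exact maximiser; Q is a lower bound on the optimum (verified against
  exhaustive partitions for N ≤ 8 and Louvain on larger graphs).
* Small-world propensity uses a single null pair per evaluation; its
  per-subject noise is visible in cohort correlations.
* The zero-lesion log-load floor is a convention; analyses of cohorts
  with many lesion-free subjects should check sensitivity to it.
* The 10 mm rule measures centre-to-centre voxel distance, not distance
  to the ventricular surface mesh.
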