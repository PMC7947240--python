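# Methods

This note records the models, numerical conventions and design choices
behind brainmkl, and what the synthetic-data tests do and do not
demonstrate.

## Network construction

**Morphological.** Each region's gray-matter density samples are turned
into a discrete distribution by a Gaussian kernel-density estimate with
Silverman's bandwidth, evaluated on a shared 128-point grid spanning the
pooled sample range of all regions and renormalized to sum to one. The
edge weight is `exp(-[KL(p||q) + KL(q||p)])`, computed after adding
ε = 1e-10 to every bin and renormalizing, so zero bins never produce
infinities and the measure is continuous in its inputs. For two Gaussians
with common variance σ² and mean gap Δ, the symmetric KL is Δ²/σ², so the
weight decays as `exp(-Δ²/σ²)`; KDE smoothing inflates the effective
variance to σ² + h², biasing the weight slightly upward (at 10⁴ samples,
h² ≈ 0.025 σ², well inside the ±0.03 tolerance used in the tests). A
region whose samples have zero spread is rejected as an input error rather
than silently assigned a similarity. Grid size, bandwidth rule and minimum
sample count live in `DensityEstimatorConfig`.

**Functional.** Pearson correlation of the regional time series, full
correlation (no partialling, no global-signal regression), diagonal stored
as zero. Raw r is used as the edge feature; a Fisher-z variant was
considered and left out because the downstream linear kernel standardizes
each edge anyway, making the monotone reparameterization nearly neutral at
these correlation magnitudes.

**Anatomical.** Directed region-to-region connection probabilities are
taken as given (upstream tractography is out of scope) and symmetrized by
the arithmetic mean of the two directions.

Edges are the strictly-upper-triangular entries in row-major order; the
edge ↔ (i, j) map is fixed and shared by all subjects and modalities.
Region indices are 1-based in files, 0-based in memory.

## The dual solver

The soft-margin dual on the precomputed mixed kernel is solved by SMO with
first-order working-pair selection (maximal KKT violating pair over the
"up"/"down" index sets), the standard two-variable analytic update with
box clipping, a curvature floor of 1e-12 for numerically flat pairs,
stopping tolerance 1e-6 on the violation gap and an iteration cap of 1e5.
The bias is the mean of `-y_i G_i` over free support vectors
(0 < α_i < C), falling back to the midpoint of the violation interval when
no free vector exists. The inner loop is numba-JIT-compiled; a pure-Python
path with identical arithmetic runs when numba is absent, so results do
not depend on the backend. Inner-CV candidate fits use a looser tolerance
(1e-4) since only the predicted signs enter model selection; final fits
use 1e-6.

Two independent audit routes live in `brainmkl.diagnostics`: a
constraint-eliminated brute-force grid search with four refinement levels
(practical for n ≤ 6), and an exact active-set enumeration of the concave
QP (3ⁿ assignments). The grid oracle is itself validated against the
enumeration in the unit tests.

## Kernel weights, C, and tie-breaking

β is chosen on the 0.1-step simplex lattice (66 candidates for three
modalities, 11 for two, 1 for one) by stratified 5-fold inner CV on the
training fold. C defaults to 1; an optional policy searches
{2⁻⁵, 2⁻³, …, 2⁵} jointly with β. Ties in mean inner accuracy are broken
toward smaller C, then the most uniform β (minimum variance), then
lexicographic order — deterministic and biased toward no modality. A
decision value of exactly zero predicts the positive (clinical) class.
Labels are encoded clinical = +1, control = −1, so sensitivity is the
detection rate of the clinical group.

Edge screening is rank-based top-k (k = 20 per modality by default) rather
than threshold-based, so every fold contributes the same feature dimension;
a warning is logged whenever a selected edge's p-value is at or above the
nominal reporting threshold (0.001 by default). Features are z-scored per
edge with training-fold statistics before the linear kernel; zero-spread
features are centered and left unscaled, contributing nothing to the
inner products.

## Synthetic cohorts

The generator emulates the statistical skeleton of a two-group (or
multi-group) multimodal MRI study: per subject, regional density samples,
region × timepoint time series, and a directed probability matrix. Defaults
are 246 regions (30 at desk scale), 240 timepoints, 200 density samples per
region. One master seed spawns per-subject substreams keyed by (group
index, subject index), so a subject's data is reproducible even when other
groups are resized, and identical spec + seed gives byte-identical cohorts.

Planted effects are specified in SD units of the *constructed edge
feature*, so d = 2 means the clinical-vs-control contrast on that network
weight is approximately a Cohen's d of 2:

* functional — time series are zero-mean multivariate normal (only their
  Pearson correlations are consumed downstream); an effect edge separates
  the groups by `d/√(T−3)` on the Fisher-z scale, the sampling SD of the
  z-transformed sample correlation at T timepoints;
* anatomical — directed probabilities are Beta draws (base mean 0.3,
  concentration 50, independent per direction so symmetrization is
  exercised); an effect shifts the clinical Beta mean by `d·sd(Beta)/√2`;
* morphological — per-subject region-mean offsets are zero-mean Gaussian
  (SD 1.5 in units of the within-region sample SD); an effect edge gives
  the two offsets a correlation ρ in the clinical group, with ρ solved by
  root-finding so the closed-form mean shift of `exp(-X²)` features equals
  d pooled SDs. Only the pair's joint law changes — every marginal is
  untouched — so non-effect edges remain distributionally identical across
  groups. The bounded similarity limits representable morphological
  effects to roughly −0.25 … +2.7 at the default offset SD (the feature
  cannot rise above 1); outside that range the spec is rejected rather
  than silently clipped. Because calibration ignores KDE smoothing and
  finite-sample noise, realized morphological contrasts run some 10–20%
  below nominal — immaterial at d = 2 with 30 subjects per group
  (planted-edge t-statistics land near 6–10).

Two plants on edges sharing a region can demand an infeasible joint
covariance (functional or morphological); the generator checks positive
semidefiniteness and rejects such specs, and `random_effect_edges` draws
disjoint pairs by default.

What the generator does **not** emulate: spatial autocorrelation and
parcellation structure, hemodynamic temporal autocorrelation, head-motion
artifacts, site/scanner effects, age/sex covariates, and realistic
between-edge dependence. Passing tests therefore demonstrate the
*machinery* — leakage-free nesting, calibrated nulls, recovery of planted
signal at stated effect sizes — not expected performance on clinical MRI,
where effect sizes are far smaller and confounds dominate.

## Study conditions used by the tests and the acceptance script

Desk scale keeps the full pipeline inside interactive budgets: 30 regions
(435 edges), 30 subjects per group, 10 planted edges per modality at
d = 2.0, nested LOOCV with 5-fold inner CV over the 66-point β lattice and
fixed C = 1. Null calibration uses 100 zero-effect cohorts of 20+20
subjects on 15 regions; the type-I-error Monte-Carlo standard error is
computed over per-seed rejection fractions because edges within a cohort
are correlated (morphological edges share region offsets). The
permuted-label chance check runs on a zero-effect cohort: on a
signal-bearing cohort a random permutation retains a hypergeometric
overlap with the true labels that a strong classifier converts into
accuracy systematically above 50%, which is a property of the design, not
of the implementation.

## Reporting conventions

Selection frequency is the fraction of outer folds choosing an edge; the
display set is the top 20 by frequency, then mean |t|, then edge index.
Direction of change is the sign of the clinical-minus-control mean on the
full cohort, with an explicit "none" for exact zeros. Contrast overlap
intersects the display sets per modality (optionally all selected edges)
and flags direction concordance. Hubs are the top 10% of regions by nodal
strength (sum of absolute edge weights); this is a stated convention — the
literature this package serves displays hubs without defining them — and
every output labels it as such.

## Known limitations

* The morphological effect calibration is analytic up to KDE smoothing;
  nominal and realized d differ by a modest, documented factor.
* Negative morphological effects are representable only over a narrow
  range (the null similarity already sits low on the bounded scale).
* LOOCV accuracy estimates have high variance at n = 60; the binomial
  standard error quoted alongside the combining-modalities comparison is
  approximate (predictions across folds are weakly dependent).
* The SMO solver targets desk-scale kernels (tens to low hundreds of
  samples); it is exact but not engineered for n ≫ 10³.
* Extremely ill-scaled features (orders of magnitude beyond standardized
  range) can slow SMO convergence near the 1e-6 tolerance; inputs are
  expected to pass through the standardization path.
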