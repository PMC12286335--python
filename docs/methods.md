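# Methods

## Scope and design

`geoscreen` implements a spatial case-control pipeline for a rare binary
outcome: polygenic risk scoring from genotype dosages, ICD-10-based case
selection with constraint-matched controls, geographically weighted
logistic regression (GWLR) with a bi-square kernel and AICc bandwidth
selection, and regional median-odds-ratio reporting. Because the cohort
this design targets is controlled-access, the package ships a
first-class synthetic-data module that generates cohorts with the
statistical structure the analysis assumes, and every stage is validated
against that generator's known ground truth.

## The synthetic cohort generator

Participants are scattered N(centre, spread²) around a configurable set
of urban centres on an arbitrary planar coordinate system — no CRS is
attached because the kernel consumes only Euclidean distances. Within a
centre, consecutive blocks of `oa_group_size` participants form an
output area sharing one exact coordinate, emulating output-area-level
geocoding and deliberately stressing the d = 0 kernel path; a jittered
mode breaks the ties for sensitivity checks, since whether real
geocoding used area centroids or per-person locations is an open design
choice.

Covariates are drawn i.i.d. from per-covariate distributions (Bernoulli,
normal, uniform, or externally supplied values — the latter lets a
computed polygenic score feed back into the outcome model). The outcome
is `y ~ Bernoulli(expit(η))` with
`η(x, y) = β₀(x, y) + Σ_k β_k(x, y)·x_k`, where each coefficient surface
is a deterministic object in one of four families chosen to span the
recovery tests: constant (null spatial variation), linear gradient
(smooth monotone), gaussian bump (smooth localized), and two-cluster
step (discontinuous). With all surfaces constant the generator reduces
to an ordinary logistic model, which is the basis of its own validation:
an independent numeric maximizer of the Bernoulli likelihood recovers
the constant coefficients within 3 standard errors at n = 10,000.

Genotypes are independent per variant (dosage `Binomial(2, freq)`, with
dosage mode adding truncated-normal noise of sd 0.1 clipped to [0, 2] —
any bounded perturbation satisfies the contract; this one is simply
documented). The generator does **not** emulate linkage disequilibrium,
imputation uncertainty, ancestry structure, kinship, or family history;
passing tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to population
stratification — a limitation the underlying study design shares.

## PRS

The score is `Σ_v dosage_sv` (unweighted, the default) or
`Σ_v w_v · dosage_sv`. The high/low dichotomy uses the empirical
`1 − f` quantile (f = 0.05) under the linear-interpolation ("type 7")
convention with a ≥ threshold, so threshold ties all land in the high
group and all-equal scores are all high. Missing panel variants fail
loudly by default; lenient mode excludes them without rescaling the
remaining weights, because rescaling would silently change what the
score measures. Dosages are assumed pre-oriented to the risk allele;
the VCF reader flips `2 − DS` when the risk allele is REF and drops
(with a warning) variants whose risk allele matches neither REF nor ALT.

## Matching

Cases are rows whose ICD-10 code is in {C18.0–C18.9, C19, C20, C26.0};
rows with any other cancer code (C\*, D0–D4\*) are ineligible as
controls. "Within a 5-year age range" is read as |Δage| ≤ 5. Matching is
greedy in seeded-random case order, drawing up to 4 controls per case
uniformly without replacement from the eligible pool (same output area
by default), each control used at most once globally; cases with no
eligible control are retained unmatched with a warning, never dropped,
since the regression stage does not require complete groups. Optimal
and frequency matching are documented non-goals. The age split keeps
age ≥ 50 in the older dataset (the cutoff is inclusive on the older
side).

## GWLR

Regression points are the observation locations, because the analysis
reports per-participant odds ratios and significant proportions. Each
local fit maximizes `Σ_j W_ij [y_j η_j − log(1 + e^{η_j})]` by IRLS with
combined weights `W_ij μ_j(1−μ_j)`, tolerance 1e−8 on the max
coefficient change, 50 iterations maximum, and the linear predictor
clipped at ±30 to guard the link against overflow. The coefficient
covariance is the inverse weighted Fisher information at the last
iterate. Degenerate local subsamples — single-class weighted outcome,
rank deficiency, singular information — yield a non-estimable fit
(flagged, coefficients empty) rather than an exception, and
non-estimable or non-converged points stay in significant-proportion
denominators as non-significant.

Model-level quantities follow the standard GWR conventions: the
effective parameter count K is the trace of the working-response hat
matrix assembled from each point's own fit (`S_ii = x_iᵀ(XᵀC_iX)⁻¹x_i
c_ii`); the global deviance stacks each observation's deviance under its
own local model; `AICc = D + 2K + 2K(K+1)/(n − K − 1)`, returning +∞
when the correction denominator is non-positive (the bandwidth is then
rejected). In the flat-kernel limit every local fit equals the global
MLE and K equals the parameter count — this equivalence, checked against
an independent BFGS maximizer of the likelihood, is the module's primary
oracle.

Bandwidth selection is golden-section search on AICc with relative
tolerance 1e−2 of the interval, ties resolved toward the larger
(smoother) bandwidth. In fixed mode the interval is [smallest bandwidth
strictly covering every point's m+2 nearest neighbours, 2 × max pairwise
distance]; in adaptive mode, integer neighbour counts in [m+2, n−1],
with the per-point bandwidth the distance to the k-th nearest neighbour.
AICc is not unimodal in pathological cases; the search returns the best
finite value seen on its trace if the bracketing minimum is non-finite.
Coordinates must be planar: column names suggesting lat/lon are rejected
with instructions to project, rather than silently switching to geodesic
distances. Significance is strict p < alpha (default 0.05) per local
Wald test, with no multiple-testing correction across locations — a
faithful-reproduction choice, since the design this follows applies a
raw 0.05 threshold.

## Reporting

Percentages print half-up at one decimal, with "100" reserved for
count = total: a proportion that would round up to 100.0 while at least
one participant is missing prints one display unit lower (99.9). This
single rule reproduces every printed cell of the published summary
tables, whose cells are not mutually consistent under plain half-up
rounding alone. Medians of even counts are the mean of the central pair.
Region assignment is point-in-polygon with `covers` (boundary points
belong to a region), first feature wins on overlap, participants outside
all polygons collect in an explicit `unassigned` region, and empty
regions report missing — never zero — medians. Choropleth class bands
are lower-open/upper-closed ((2.0, 3.0]) so each value falls in exactly
one band; the convention is stamped into the GeoJSON properties.

## Problem sizes

The analysis drivers run one fixed study: 10,000 participants, 140
variants, five centres, 20-person output areas, baseline intercept set
for ~4–5% raw prevalence, and a high-PRS gaussian-bump surface spanning
local OR ≈ 2.0–3.3 (participant-level median ≈ 2.7), sized so the whole
pipeline completes in well under a minute. Validation simulations use
500 rows (flat-kernel oracle), 2,000 (two-cluster recovery, pre-set
bands (1.5, 2.7) and (3.0, 5.3) around true ORs 2 and 4), and 300
(bandwidth search vs a 20-point grid). At the matched-dataset sizes the
driver produces (~1,400 rows), AICc prefers wide bandwidths and local
estimates are strongly smoothed; spatial contrast in the estimated
surfaces grows with cohort size, which is the expected behaviour of
kernel-local likelihoods, not an implementation artefact.

## Known limitations

Unconditional logistic analysis of a matched design recovers
exposure-outcome odds ratios only when the matching variables are
adequately represented in the model; here age enters directly and
location enters through the kernel, but a very wide selected bandwidth
conditions on location only coarsely, so matched-sample odds ratios for
spatially varying effects can attenuate toward their population-average
value at small n. Separation in sparse kernels is reported, not
penalized (no Firth correction). The bandwidth search assumes an
approximately unimodal AICc profile. No population-stratification
control is attempted for the PRS.
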