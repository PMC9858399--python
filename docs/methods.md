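# Methods

## Scope and model

The package analyzes per-subject multivariate time courses
X ∈ R^{T×C} — one column per large-scale network component (default
C = 6: dDMN, pdDMN, pvDMN, rECN, lECN, SN) sampled at TR seconds (default
2.4 s, T = 190 retained volumes). Everything upstream of these time
courses (image preprocessing, group decomposition, component selection) is
out of scope; everything downstream — conditioning, static and dynamic
connectivity, state clustering, meta-state dynamism, behavioral screens —
is implemented and tested here.

## Conditioning

Each column is (1) linearly detrended, (2) despiked, (3) low-pass
filtered, in that fixed order. Despiking replaces samples whose deviation
from a running median (window 7, odd) exceeds 3 × (1.4826 × MAD of the
column about its median) with the running-median value. The robust scale
is deliberately the column's ordinary MAD, not the MAD of the
running-median residuals: an odd-window running median reproduces the
center sample exactly on locally monotone stretches, so residual MADs
collapse to zero on smooth signals and would flag a large fraction of
ordinary points. When the scale is still zero (a flat trace), any nonzero
deviation is treated as a spike; a constant column passes through
unchanged. Filtering is a digital Butterworth low-pass (order 5, cutoff
0.15 Hz) applied forward-backward (zero phase), so window assignments
downstream are not phase-shifted; the effective magnitude response is the
squared one-pass response. Optional nuisance regression (OLS residuals
against an intercept plus user regressors) is available but off by
default: covariate adjustment belongs to the statistics stage in this
design.

## Windowed connectivity

The taper is a width-15 rectangle convolved with a Gaussian of σ = 3 TR
truncated at ±8 TR, peak-normalized; support L = 15 + 2·8 = 31 TR. The
truncation is chosen so 190 timepoints yield exactly 160 windows at step
1 (W = T − L + 1). Within each window the taper acts as observation
weights: weighted means and covariances give a weighted Pearson matrix.
A zero weighted variance sets the affected pairs to r = 0 with a warning.

With the graphical-LASSO estimator, each window's weighted covariance is
replaced by the L1-penalized maximum-likelihood covariance
(scikit-learn's solver) before conversion to correlation; λ = 0
short-circuits to the sample path exactly. The penalty is selected per
subject by K-fold cross-validation (default 5 contiguous window blocks,
respecting temporal ordering of overlapping windows): for each λ on a
10-point log grid over [10⁻³, 1], the precision fit on the averaged
training-window covariance is scored by log det Θ − tr(S Θ) on each
held-out window covariance; ties go to the smallest λ, and a λ whose fit
fails anywhere is excluded.

## State clustering and metrics

All subjects' window vectors (the P = C(C−1)/2 upper-triangle entries)
are pooled and clustered by Lloyd iteration under the Manhattan distance:
nearest-centroid assignment (ties to the lowest index), componentwise
median update (the L1 minimizer), emptied clusters re-seeded from the
point farthest from its centroid. Each fit is the best of 10 uniformly
seeded replicates (lowest total within-cluster L1 distance), capped at
200 iterations. No exemplar-window prefiltering is applied; clustering
runs on all windows.

k is selected over 2..8 by the elbow of the cluster index
I(k) = (mean within-cluster distance to centroid) / (mean pairwise
centroid distance): the chosen k maximizes the *signed* gap below the
chord joining (2, I(2)) and (8, I(8)); points above the chord never win,
endpoints tie at zero and ties resolve to the smaller k. The signed form
matters: an absolute distance can never return an endpoint, so a dataset
whose true structure sits at k_min would be mis-selected by construction.
Even so, endpoint truths are only majority-recoverable: splitting a
Gaussian cluster halves its within-spread while the between-centroid mean
shrinks more slowly, so I(k) lacks a sharp endpoint elbow.

Per-subject metrics from the 1-based state labels: FT_k (fraction of
windows in k), MDT_k (mean maximal-run length of k, reported in windows;
seconds = windows × step × TR on request), NT (adjacent label changes).
Conservation laws — ΣFT = 1, Σ(runs × MDT) = W, NT ≤ W − 1 — are enforced
by tests. Subjects who never enter a state carry FT = MDT = 0 in metric
tables but are excluded from that state's connectivity screen; a
subject's per-state connectivity summary is the elementwise median of its
windows assigned to the state.

## Meta-states

Pooled window vectors are decomposed by fixed-point ICA (PCA whitening to
m components, then the independence-maximizing rotation) into m
connectivity patterns; m defaults to 4, mirroring the default state
count, and is configurable — the dimensionality is a design choice, not an
estimated quantity. Reproducibility across runs comes from a fixed
orientation convention: each pattern's largest-magnitude element is made
positive and patterns are ordered by contributed variance. Per-window
weights are discretized per pattern into sign(weight) × quartile(|weight|)
with boundaries at the 25/50/75th percentiles of |weight| pooled over the
whole cohort (pooling keeps meta-state vectors comparable between
subjects); boundary ties take the lower quartile and an exact zero codes
as +1, so codes lie in {−4..−1, 1..4} and never 0. The four indices per
subject: distinct meta-states occupied, changes between successive
meta-states, span (largest L1 distance between occupied meta-states) and
total L1 distance traveled.

## Behavioral statistics

Screens are plain Pearson correlations (two-sided p from t with n − 2 df)
between connectivity features and the six behavioral measures, with
Benjamini–Hochberg FDR at q = 0.05 per declared family. The step-up is
implemented with an explicit family size m ≥ (number of computed tests):
adjusted p_(i) = min_{j≥i} m·p_(j)/j capped at 1, which reduces to the
standard correction at m = len(p) and is strictly conservative for larger
declared families. The per-state connectivity family defaults to
pairs × states × measures (15 × 4 × 6 = 360); the state-metric and
meta-state families default to the literal number of tests run, with the
family size configurable where a larger declared family is wanted.
Fisher's z is applied to per-state correlations before screening
(variance stabilization). Naming covariates switches the screen to
partial correlations (both sides residualized by OLS, t on n − 2 − k df).
Degenerate tests (fewer than 3 complete pairs, or a constant side) are
skipped with a warning rather than aborting the screen. Motion QC
correlates per-state fraction time against mean framewise displacement,
reported raw (flagged at p < 0.05, no FDR) as a screen, not a test family.

## Synthetic cohorts

The generator emulates the study conditions: 80 subjects × 190 timepoints
× 6 components at TR 2.4 s. Latent states follow a first-order Markov
chain (default self-transition 0.90, uniform off-diagonal → geometric
dwells of mean 10 TR); emissions are i.i.d. zero-mean Gaussians with the
active state's correlation matrix, so windowed correlations are unbiased
for the state matrix. The four default templates qualitatively render the
recurring patterns: (1) a posterior-DMN/ECN ensemble with a silent
salience row, (2) DMN–ECN antagonism with moderate DMN–SN coupling,
(3) global hyperconnectivity, (4) an isolated strong pvDMN–SN dyad with
both members anticorrelated with the otherwise coherent remainder. A
single `separation` scalar (default 0.6) scales all off-diagonals; any
template that is not positive definite is repaired by eigenvalue clipping
at 10⁻⁶ and diagonal rescaling. The 1–4 anticorrelation is load-bearing:
rendered as zeros instead, states 1 and 4 sit ~2.8 apart in L1 over the
15 pairs — the same magnitude as within-state window noise under the
31-TR taper — and the elbow merges them.

Behavioral scores are drawn around the cohort's published means/SDs
(YSR T-scores ≈ 57 ± 7, UPPS facets ≈ 2–2.8 ± 0.65) as
b = mean + sd·(Σᵢ ρᵢ·z(fᵢ) + √(1 − Σρᵢ²)·ε) against ground-truth dynamic
features (true-state FT/MDT, transition count, and per-subject
connectivity-edge offsets injected into a named state's matrix). The
default effect set plants the study-sized effects: lECN~SN edge in state
1 vs both attention measures (ρ = −.39/−.38), state-3 dwell vs ADHD and
perseverance (.30/.33), and a single switching-rate effect vs ADHD
(ρ = .35) standing in for the two meta-state dynamism effects, which are
both monotone in switching frequency and would otherwise require two
effects on one (feature, behavior) pair. A null lognormal mean-FD column
supports the motion QC screen.

What the synthetic cohort does **not** emulate: hemodynamic
autocorrelation and spectral coloring, within-state temporal dynamics,
scanner drift/physiological noise (beyond what conditioning removes),
subject-level state-preference heterogeneity, and non-Gaussian BOLD
amplitude distributions. Passing tests certify the pipeline's mechanics
and statistical calibration under the stated generative model — not that
real data would yield the same states or effect sizes.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to make their statistical bounds
sharp while staying desk-scale: model-selection recovery uses 20
replicate 40-subject cohorts (6400 pooled windows each), planted-effect
recovery 200 cohorts per effect size at n = 80, FDR calibration 1000
null families of 360 tests, and power ranking 100 cohorts. Monte-Carlo
tolerances follow the usual sampling bounds (e.g. |r̂ − ρ| ≤ 2/√n,
binomial 3-SE allowances on empirical rates). Determinism: every
stochastic step (cohort generation, k-means replicates, ICA, CV folds)
is driven by explicit integer seeds; identical config + seed reproduces
artifacts checksum-identical.

Known limitations: the elbow rule inherits the flatness of the
within/between index when clusters are mixtures (short dwells relative to
the 31-TR window blur windowed estimates toward state averages); the
graphical-LASSO solver can fail on near-singular windows, in which case
the sample estimate is used with a warning; and meta-state indices depend
on the configured pattern count m, which has no empirical estimator here.
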