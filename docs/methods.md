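# Methods

This note documents the models, parameter choices and numerical
decisions behind `restdyn`, and what its synthetic validation does and
does not demonstrate.

## The synthetic cohort generator

The generator is the package's substitute for patient data: it produces
two-group cohorts with exactly the statistical structure the analysis
stages assume, plus per-subject ground truth for parameter-recovery
testing.

**State dynamics.**  Each subject follows a K-state Markov chain
(K = 6 by default).  Given a target occupancy profile π and switching
rate r, the transition matrix is the reversible closed form

    A[i, j] = c·π[j]  (j ≠ i),   A[i, i] = 1 − c·(1 − π[i]),
    c = r / (1 − Σ_k π_k²),

whose stationary distribution is π and whose expected per-step switch
probability is exactly r (Σ_i π_i (1 − A_ii) = r).  Defaults emulate
the study conditions: 110 patients vs 106 controls, r = 0.08 vs 0.06,
uniform baseline occupancy with the patient profile shifted +0.06 on
state 1 and −0.03 on states 3 and 6 (the reported directions; the
magnitudes are a design choice since only directions and significance
are reported).  Infeasible (π, r) pairs — any negative self-transition
— raise a parameterization error naming the maximum feasible rate.
r = 0 is legal and yields constant paths; the occupancy target is then
met at the ensemble level through the initial-state distribution.

**Emissions.**  Observation = state mean + band-limited drift + white
noise.  State means are i.i.d. N(0, 1) spatial patterns shared by both
groups (diagonal-covariance Gaussian emissions keep the desk-scale HMM
recovery well-posed).  Band-limited content in 0.01–0.1 Hz is injected
as *additive* drift (sd 0.3) rather than by low-pass filtering the
state modulation itself: smoothing the modulation would smear state
transitions, bias the ground-truth switching rate, and break the
Gaussian-emission assumption the HMM stage relies on.  With ~20 or more
parcels the inter-state pattern distance (≈ √(2N) in noise units)
dominates the noise, which is what makes Viterbi decoding — and hence
switching-rate recovery — accurate.

**Planted deficits.**  In patients, affected parcels (defaults:
hippocampal/orbitofrontal/superior-parietal AAL indices at 90 parcels,
~15% of parcels otherwise; amplitude factor α = 0.6) have their signal
part scaled by α while measurement noise stays at full strength — this
lowers the band share of the spectrum (fALFF) and inter-regional
correlations (degree centrality).  When volumes are rendered, the same
parcels additionally receive independent voxel noise of sd
√(1 − α²), which lowers within-parcel rank concordance (ReHo).  The
effect sizes are calibrated so the default cohort sits in the
separability regime the emulated study reports (AUC ≈ 0.85 for the
nonlinear kernels); directions, not magnitudes, are the claim.

**Volumes.**  The lattice atlas is built by chunking a boustrophedon
traversal of the voxel grid into near-equal face-connected regions of
at least 27 voxels (the default 15³ grid hosts 90 parcels at 37–38
voxels each).  Every voxel carries its region's time course plus
independent voxel noise (sd 0.5), so noise-free volumes round-trip to
the node series exactly under parcel-mean extraction.

**What the generator does not emulate:** scanner physics, head motion,
physiological noise, spatial autocorrelation beyond parcel membership,
hemodynamic convolution, or structural (VBM) differences.  Passing
recovery tests therefore shows the *pipeline* is correct and sensitive
to the planted structure, not that real data would yield these effect
sizes.

## Preprocessing

In-scope temporal steps only: drop the first 10 volumes (240 → 230),
remove each column's least-squares line, and restrict to 0.01–0.1 Hz
with an ideal FFT-domain filter (bins at exactly 0.01/0.1 Hz are
retained; DC always removed).  The full chain applies trend and
out-of-band removal as a *single* orthogonal projection onto the
complement of span{1, t, out-of-band Fourier modes}: sequential
detrend-then-filter is not idempotent (a finite-window sinusoid carries
an O(10⁻³) linear-trend component, so a second pass keeps changing the
output), whereas the joint projection is exactly idempotent, which
downstream code and tests rely on.  The ideal filter was chosen over an
IIR family for exact testability (Parseval-tight band power, exact
idempotence).

## Static features

fALFF is computed on detrended but unfiltered series — its denominator
spans the entire positive-frequency axis and would be distorted by
prior band-passing.  Both band limits are inclusive.  The default
spectrum statistic is the **power** (energy) fraction; the classic
amplitude-sum convention is available via `spectrum="amplitude"`.  The
power form was chosen because the amplitude ratio is dominated by
spectral leakage for narrowband signals (a pure 0.02 Hz tone at
T = 230, TR = 2 s scores only 0.58 by amplitude but 0.98 by power);
for broadband signals the two agree in expectation (white-noise value =
band-bin fraction either way).  Flat series get fALFF 0 with a
degeneracy flag.

ReHo uses Kendall's W over the 27-voxel neighborhood (7/19 available),
average ranks for ties and no tie correction, with edge voxels using
their available in-mask neighbors (K adjusted; no padding).  Degree
centrality thresholds Pearson r at 0.25 (a common toolbox default; the
source analysis does not state one) and excludes negative correlations;
zero-variance voxels get no edges and a flag.  Feature maps are not
z-standardized before parcel averaging — scaling is left to the
classifier's per-fold standardizer.  In node mode (only parcel series
available) fALFF and degree centrality are computed on the node graph;
ReHo has no node-level definition and raises if requested.

## Multilayer modularity and node flexibility

Windowed Pearson networks use a rectangular window of 40 TRs and
overlap 0.975, giving step = round(40 × 0.025) = 1 TR and
L = ⌊(T − 40)/1⌋ + 1 = 191 layers at T = 230.  Negative window
correlations are truncated to zero (the Newman–Girvan null assumes
non-negative weights); per-layer strengths and 2m_s are computed on the
truncated matrices; a zero-weight layer contributes no null term and is
flagged.

The optimizer is GenLouvain-style: the sparse supra-modularity matrix
(dense intra-layer blocks, ω on the ±N diagonals for ordinal coupling
of adjacent layers) is maximized by repeated greedy single-node moves
(numba-compiled sweep; a node may also leave for a fresh singleton
community) followed by community aggregation, until no move improves
Q.  Three seeded restarts with shuffled sweep order are run and the
best Q kept; Q is asserted non-decreasing across passes.  On tiny
instances the optimizer attains the exhaustively enumerated optimum
(verified over seeded runs in the tests).  Labels are globally
consistent across layers by construction, so flexibility is simply the
per-node fraction of adjacent-layer label changes.  The 3×3 (γ, ω)
grid yields 9 NF values per parcel, each grid cell with an independent
child seed.

## HMM state dynamics

One group-level model — not per-subject fits, which would make
occupancies incomparable across subjects.  Series are z-scored per node
within subject (constant nodes map to zero), concatenated with subject
boundaries respected so no transition is learned across subjects, and
fitted by EM via `hmmlearn` with diagonal covariances (full covariance
optional) and a 10⁻⁶ covariance floor.  Convergence: log-likelihood
gain below 10⁻⁶ per frame, or 500 iterations; the full LL trace is
recorded and its monotonicity asserted.

Restart design: the first restart initializes means by k-means, but
k-means is nearly deterministic across seeds, so *additional* restarts
draw initial means from randomly chosen observation frames.  This
matters in practice — with only reseeded k-means all restarts can fall
into the same local optimum in which two fitted states duplicate one
true state and Viterbi ping-pongs between them, grossly inflating the
switching rate; a diverse restart finds the higher-likelihood basin and
the best-final-LL rule selects it.

FO/SR use hard Viterbi assignments (occupancy as the fraction of the T
decoded time points per state; switching rate as transitions/(T−1),
i.e. a per-step fraction, consistent with reported group means of
0.06–0.08); posterior-averaged FO is available behind a flag.

## Feature table, selection, classification

The assembled table has a fixed column order — five static blocks of N
parcels, nine NF blocks, FO1..FOK, SR — 1,267 columns at the reference
dimensions (90 parcels, 3×3 grid, K = 6).  Missing subjects or NaNs
are hard errors; no imputation.  TSV output carries a JSON sidecar with
a config hash for provenance, and reads round-trip bit-exactly.

Selection always sees training subjects only; the CV driver re-runs it
per fold.  The Spearman rule keeps ⌈0.01·P⌉ features (minimum 1; ties
broken by column order), hence exactly 13 of 1,267.  The LASSO path is
interpreted as a 100-point log-spaced penalty path (the toolbox
convention behind "lambda = 100"; a literal penalty of 100 is not
interpretable), with the penalty chosen by inner 5-fold deviance and an
explicit flagged fallback to the weakest penalty keeping at least one
feature.  The t-filter uses Student's equal-variance test at p < 0.05
with no multiplicity correction (mirroring the emulated analysis);
Welch's test is a flag away.

SVMs use C = 1, degree 3 and `gamma='scale'` (the source reports no
hyperparameters; these are the scikit-learn conventions), features
standardized on each training fold.  AUC is the Mann–Whitney rank
statistic (ties ½); accuracy/sensitivity/specificity threshold the
decision value at 0; reported values are fold means.  The permutation
test re-runs the *entire* pipeline — fold split, selection, fit — per
label permutation, p = (1 + #{perm ≥ observed})/(n + 1); a frozen-
selection fast mode exists for comparison only and is never used for
inference.

## Scale presets and problem sizes

The `full` preset pins the full emulated study (110/106 subjects, 90
parcels, 240 volumes, 5,000 permutations) and is hours-scale.  The
`desk` preset — 20/20 subjects, 20 parcels, a 9³ voxel grid, 200
permutations — runs in about a minute on one CPU and is the size at
which the end-to-end properties (determinism, planted-effect
separability, permutation calibration) are exercised.  Recovery tests
use the smallest sizes at which the claims are stable: switching-rate
emulation uses 200 subjects/group at 20 parcels (SR recovery is
parcel-count-agnostic once states are well separated); HMM parameter
recovery uses 3 states × 10 nodes × 40 subjects × 500 time points;
exhaustive modularity checks use ≤9 supra-nodes, where full partition
enumeration is feasible.

## Known limitations

- The multilayer optimizer is greedy; global optimality is only
  guaranteed (and only verified) on tiny instances.
- Gaussian-HMM recovery degrades when state patterns are weakly
  separated (few parcels, strong drift); the diverse-restart scheme
  mitigates but cannot eliminate local optima.
- Node-mode runs omit ReHo, so the assembled table is smaller than the
  reference 1,267 columns in that mode by design.
- Windowed correlations use a rectangular window; no tapering.
- The permutation test at desk scale (200 permutations) bounds p from
  below at 1/201; the full preset uses 5,000.
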