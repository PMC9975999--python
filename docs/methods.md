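# Methods

## Phenotype derivation

Trial-level data carry one expectancy rating (integer 1–9) per participant ×
phase × stimulus × trial. Three differential phenotypes are defined as
CS+ minus CS− window means: initial development (acquisition trials 1–4 per
stimulus), consolidation (acquisition 9–12) and extinction (extinction 1–6).
"Thirds" are counted per stimulus, not over the interleaved presentation
sequence; with 12 and 18 trials per stimulus the acquisition windows span 4
trials and the extinction windows 6. A late-extinction window (13–18) is
available for descriptives but excluded from modelling — by late extinction
nearly all participants rate both stimuli at floor and the score carries
almost no variance.

A window mean requires at least half its trials rated per stimulus;
otherwise the phenotype is missing (not an error). This keeps participants
with sporadic skips without biasing window means, and missingness is later
absorbed by FIML rather than imputation.

Compliance exclusions remove all trials of participants who removed their
headphones, reduced volume below 50% or exited the app; reasons are tallied
non-exclusively but each participant is removed once.

Scores are residualized on intercept + age + sex by ordinary least squares
(min-norm solve, so a degenerate design — uniform age and sex — collapses to
mean-centring), then transformed by the signed square-root
sign(x)·√|x|. The transform choice matters: differential-score residuals are
signed, and the signed square-root is the only square-root variant that is
defined on the whole line, odd, and strictly order-preserving. Residuals are
invariant to which sex is the reference level. A zero-variance score returns
centred values with a warning rather than failing.

## Twin descriptives

All pair-level correlations use **double entry**: each complete pair enters
in both orderings, making the intraclass correlation (ICC) exactly invariant
to twin labelling and numerically identical to the diagonal of the
cross-twin cross-trait matrix. The descriptives are moment-based (no
saturated SEM). Singletons contribute to phenotypic correlations and means
only. Bootstrap CIs resample whole families with replacement, stratified by
zygosity, percentile method, 100 iterations by default; a statistic failing
on more than 20% of resamples aborts with a diagnostic count.

## Biometric model

Per-component covariances are parameterized by lower-triangular Cholesky
factors (6 free entries each), guaranteeing positive semi-definiteness for
any parameter value: AE has 12 covariance parameters + 3 means, ACE 18 + 3.
One mean per trait is equated across twin order and zygosity — phenotypes
are pre-residualized, so saturated means testing adds nothing and is out of
scope. DZ genetic sharing is fixed at 0.5.

The FIML objective sums, over families, the −2 log multivariate-normal
density of each family's observed subvector under the zygosity-appropriate
implied moments. Internally, families are grouped by (zygosity, missingness
pattern) and each group's contribution is computed from sufficient
statistics (N, Σx, Σxxᵀ), which is algebraically identical to the
per-family sum (unit-tested against a per-family density oracle at 1e-8)
and makes each evaluation O(1) in the number of families. A numerically
singular implied covariance yields a large finite penalty (1e12) instead of
an exception, so line searches can back off.

The analytic gradient is supplied: with W = Σ⁻¹ on a pattern's observed
entries and M = Σᵢ W rᵢrᵢᵀ W, the derivative of the objective with respect
to that Σ block is N·W − M; the blocks fold into component-level gradients
G_A, G_C, G_E through the MZ/DZ structure (the cross-block weight α scales
the A fold), and ∂f/∂L = 2·G·L restricted to the lower triangle. The
gradient is verified against central finite differences in the tests.

Optimization uses L-BFGS-B with analytic gradients, a Falconer-based start
(double-entry twin correlations → clipped moment estimates of a², c², e²,
component covariances scaled by the pooled phenotypic correlation matrix),
and up to 5 jittered restarts if the first attempt does not converge.
Convergence requires the gradient norm scaled by max(1, |−2lnL|) below 1e-5
together with the optimizer's relative-improvement criterion; an absolute
gradient cutoff would be below numerical resolution at objective magnitudes
of ~1e4. ACE start values floor c² at 0.05 because L_C = 0 is a stationary
point of the Cholesky parameterization. Post-fit, Cholesky columns are
sign-flipped so diagonals are non-negative — a pure convention, since
A = LLᵀ is invariant to column sign flips (tested).

Standardization to the correlated factors solution: a²ᵢ = Aᵢᵢ/Sᵢᵢ,
r_A,ij = Aᵢⱼ/√(AᵢᵢAⱼⱼ), contribution of A to the phenotypic correlation
contrib_A,ij = Aᵢⱼ/√(SᵢᵢSⱼⱼ), and analogously for C and E; contributions sum
to the phenotypic correlation exactly. Correlations of a zero-variance
component are reported missing; sampling-inflated values are reported as
computed and truncated only in displays.

ACE→AE comparison: χ² = Δ(−2lnL) on 6 df (the dropped C loadings), plus
ΔAIC. No boundary-of-parameter-space mixture correction is applied to the
χ² reference — the conventional, slightly conservative practice in this
literature; a documented limitation. Model CIs are percentile bootstrap over
zygosity-stratified family resamples, each refitted starting from the
full-data solution; non-converged resamples are dropped and counted, >20%
failures aborts. Profile-likelihood CIs are not implemented.

## Synthetic data generator

The generator defines ground truth as standardized variance shares (a², c²,
e² summing to 1 per trait) with component correlation matrices, checked PSD
at construction, on a standardized scale (mean 0, variance 1 — the analysed
residual-transformed scale is arbitrary anyway). The default preset encodes
the published point estimates: AE with a² = (0.15, 0.29, 0.15),
r_A = (0.99, 0.42, 0.44) pairwise, r_E = (0.49, 0.31, 0.41), and a sample
plan of 250 MZ pairs, 288 DZ pairs and 860 singletons. The r_E assignment
deserves a note: the source prints only ranges (0.31–0.49), so the pairwise
placement — 0.49 initial–consolidation, 0.31 initial–extinction, 0.41
consolidation–extinction — is a documented, configurable default consistent
with those ranges. Singletons carry a zygosity label split 400 MZ / 460 DZ
(proportional to the pair counts; the source gives only the total).

Phenotype-level simulation draws complete pairs from the 6-variate normal
with the zygosity-appropriate implied covariance (via an eigendecomposition
factor, so exactly singular structures such as e² = 0 reproduce identical MZ
co-twins to machine precision) and singletons from the 3-variate margin.
Each sample-plan section (MZ pairs, DZ pairs, singletons per zygosity) draws
from its own seeded child stream in family order, so enlarging one section
leaves all previously drawn families unchanged.

Trial-level simulation maps each participant's latent standard-normal
phenotypes to raw differential targets (mean + s.d.·z with defaults
(2.35, 4.5, 2.0) and (2.0, 2.0, 1.8); the initial-development mean matches
the published per-stimulus descriptives, 6.05 − 3.70, and differential
s.d.s near 2 follow from per-stimulus s.d.s of ~1.6 under modest CS+/CS−
correlation). Per-trial differentials follow a logistic rise during
acquisition and an exponential decay during extinction, affinely anchored
so the window means reproduce the targets exactly before noise. CS+ and CS−
trajectories sit at ± half the differential around a common expectancy
level, shifted per trial to keep both on the 1–9 scale (otherwise ceiling
clipping attenuates large differentials). Ratings add Gaussian noise
(s.d. 0.7), then round and clip to 1–9; the CS+ is reinforced on exactly 9
of 12 acquisition trials; the presentation order is pseudo-random with at
most 2 identical consecutive stimuli (the source's exact ordering rules are
unavailable; this cap is a stand-in assumption).

### What the generator does and does not emulate

It emulates the family structure, missing co-twins, the AE covariance
structure, the task design (trial counts, 75% reinforcement, rating scale)
and rating discretization. It does not emulate real response styles (anchor
use, drift, inattention), learning heterogeneity beyond the latent
phenotypes, item-level autocorrelation, dropout behaviour (exclusion flags
are injectable at configurable rates but default to none), or age/sex
effects unless configured. Passing recovery tests therefore demonstrate
estimator correctness and calibration under the assumed data-generating
process, not robustness to real-data pathologies.

## Problem sizes and numerical choices

The recovery study uses 200 replicates at the study's own sample plan, with
the AE (and where relevant ACE) model fitted to each; the sufficient-
statistic likelihood with analytic gradients makes a full fit take a few
tens of milliseconds, so the study completes in well under a minute.
Bootstrap-coverage calibration uses 200 replicates of a reduced plan
(100 MZ + 100 DZ pairs + 60 singletons) with 100 bootstrap refits each —
20,000 fits — chosen so the nested simulation remains a routine desk-scale
run. Falconer-consistency checks use 50,000 pairs per zygosity where the
moment estimator's error is dominated by the 0.02 check tolerance.

Known numerical choices: double-entry correlations rather than ANOVA ICC
(identical up to d.o.f. factors, exactly order-invariant); percentile
rather than BCa bootstrap; L-BFGS-B rather than a derivative-free optimizer
(the analytic gradient makes quasi-Newton both faster and more reliable);
ties in the consecutive-stimulus shuffle resolved by rejection sampling
with a deterministic alternating fallback.

## Known limitations

- The χ² reference for the ACE→AE test ignores the boundary mixture, making
  the test conservative.
- Under the trivariate Cholesky the fitted C factor almost never hits the
  exact zero matrix; on AE-generated data each ĉ² is therefore a small
  positive value slightly more than half the time, with magnitude of order
  its sampling s.e. (a property of the boundary-constrained MLE, not of the
  optimizer — verified by likelihood polishing and truth-started refits).
- Genetic correlations are constrained to [−1, 1] by construction, so a
  generating value near 1 (initial development–consolidation) yields a
  slightly downward-biased median estimate at finite n.
- Sex-limitation, ADE and gene–environment interaction models are out of
  scope; opposite-sex DZ pairs are pooled with same-sex DZ after sex
  residualization.
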