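"""Trivariate Cholesky ACE/AE twin models fitted by full-information maximum
likelihood (FIML), with the correlated-factors standardization.

Model
-----
For traits ``(initial, consol, extinct)`` the 3x3 component covariance
matrices are parameterized as ``A = L_A L_A'``, ``C = L_C L_C'``,
``E = L_E L_E'`` with lower-triangular ``L`` (so each component is positive
semi-definite by construction). A twin pair's 6-vector (twin 1 traits, twin 2
traits) is multivariate normal with

* within-twin covariance  ``S = A + C + E`` on both diagonal blocks,
* cross-twin covariance   ``alpha * A + C``,  alpha = 1 (MZ), 0.5 (DZ),

reflecting that monozygotic twins share all segregating genes and dizygotic
twins about half, while both share their rearing environment. One mean per
trait is equated across twin order and zygosity (phenotypes enter
pre-residualized). The AE variant drops C (12 covariance parameters + 3
means; ACE has 18 + 3).

FIML handles incomplete families without imputation: each family contributes
the normal density of its observed subvector, with the implied mean and
covariance subsetted to the observed entries, so singletons and participants
with missing phenotypes enter naturally.

The fitted Cholesky solution is re-expressed as the correlated factors
solution: standardized variance components (a2, c2, e2 per trait), component
correlation matrices (rA, rC, rE), and the split of each phenotypic
correlation into its A/C/E contributions.

Implementation notes
--------------------
Families are grouped by (zygosity, missingness pattern) and the likelihood is
evaluated from per-group sufficient statistics (N, sum x, sum x x'), which is
algebraically identical to the per-family sum but O(1) in sample size per
evaluation. The analytic gradient with respect to the Cholesky entries and
means is supplied to the optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trial_phenotypes import TRAITS
from . import twin_descriptives as td

__all__ = [
    "ModelSpec",
    "CholeskyParams",
    "FitResult",
    "CorrelatedFactorsSolution",
    "family_groups",
    "implied_covariance",
    "neg2_log_likelihood",
    "fit_model",
    "standardize",
    "compare_models",
    "falconer_estimates",
    "bootstrap_model_ci",
]

_TRIL = np.tril_indices(3)
_LN2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1.0e12


@dataclass(frozen=True)
class ModelSpec:
    """Variant and fixed constants of the biometric model."""

    variant: str = "AE"  # "ACE" or "AE"
    traits: tuple = TRAITS
    dz_alpha: float = 0.5  # DZ additive-genetic sharing

    def __post_init__(self):
        if self.variant not in ("ACE", "AE"):
            raise ValueError(f"unknown model variant {self.variant!r}")

    @property
    def has_c(self) -> bool:
        return self.variant == "ACE"

    @property
    def n_params(self) -> int:
        """Free parameters: 6 per Cholesky factor plus 3 means."""
        return (18 if self.has_c else 12) + 3


@dataclass
class CholeskyParams:
    """Lower-triangular Cholesky loadings per component plus trait means."""

    L_A: np.ndarray
    L_E: np.ndarray
    mu: np.ndarray
    L_C: np.ndarray | None = None  # None for AE

    def component(self, which: str) -> np.ndarray:
        L = {"A": self.L_A, "C": self.L_C, "E": self.L_E}[which]
        if L is None:
            return np.zeros((3, 3))
        return L @ L.T

    def to_vector(self, spec: ModelSpec) -> np.ndarray:
        parts = [self.L_A[_TRIL]]
        if spec.has_c:
            if self.L_C is None:
                raise ValueError("ACE spec requires L_C")
            parts.append(self.L_C[_TRIL])
        parts.append(self.L_E[_TRIL])
        parts.append(np.asarray(self.mu, float))
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, theta: np.ndarray, spec: ModelSpec) -> "CholeskyParams":
        theta = np.asarray(theta, float)
        if theta.size != spec.n_params:
            raise ValueError(f"expected {spec.n_params} parameters, got {theta.size}")

        def unpack(v):
            L = np.zeros((3, 3))
            L[_TRIL] = v
            return L

        L_A = unpack(theta[0:6])
        pos = 6
        L_C = None
        if spec.has_c:
            L_C = unpack(theta[6:12])
            pos = 12
        L_E = unpack(theta[pos:pos + 6])
        mu = theta[pos + 6:pos + 9].copy()
        return cls(L_A=L_A, L_E=L_E, mu=mu, L_C=L_C)


@dataclass
class FitResult:
    """Outcome of a FIML fit."""

    params: CholeskyParams
    spec: ModelSpec
    minus2LL: float
    n_params: int
    converged: bool
    n_iter: int
    grad_norm: float
    data_summary: dict = field(default_factory=dict)

    @property
    def AIC(self) -> float:
        return self.minus2LL + 2.0 * self.n_params


@dataclass
class CorrelatedFactorsSolution:
    """Standardized re-expression of a Cholesky fit.

    ``a2 + c2 + e2 = 1`` per trait; ``contrib_A + contrib_C + contrib_E``
    equals the phenotypic correlation matrix elementwise. Component
    correlations with zero component variance are NaN. ``cis`` maps quantity
    name -> (lower, upper) arrays when bootstrap CIs are attached.
    """

    a2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    rA: np.ndarray
    rC: np.ndarray
    rE: np.ndarray
    r_phenotypic: np.ndarray
    contrib_A: np.ndarray
    contrib_C: np.ndarray
    contrib_E: np.ndarray
    cis: dict = field(default_factory=dict)
    boot_info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# data preparation: missingness-pattern groups with sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class _PatternGroup:
    zygosity: str
    obs: np.ndarray      # observed indices within the 6-vector
    n: int               # number of families with this pattern
    s: np.ndarray        # sum of observed subvectors, (k,)
    m2: np.ndarray       # sum of x x', (k, k)
    x: np.ndarray        # raw observations, (n, k) — kept for oracles/tests


def family_groups(table: pd.DataFrame) -> list[_PatternGroup]:
    """Group family rows by (zygosity, missingness pattern) and precompute
    the sufficient statistics the FIML objective needs."""
    cols = [f"t1_{t}" for t in TRAITS] + [f"t2_{t}" for t in TRAITS]
    groups: list[_PatternGroup] = []
    for zyg in ("MZ", "DZ"):
        vals = table.loc[table["zygosity"] == zyg, cols].to_numpy(float)
        if vals.size == 0:
            continue
        mask = ~np.isnan(vals)
        keep = mask.any(axis=1)
        vals, mask = vals[keep], mask[keep]
        if len(vals) == 0:
            continue
        codes = mask @ (1 << np.arange(6))
        for code in np.unique(codes):
            rows = vals[codes == code]
            obs = np.flatnonzero(mask[np.argmax(codes == code)])
            x = rows[:, obs]
            groups.append(_PatternGroup(
                zygosity=zyg, obs=obs, n=len(x),
                s=x.sum(axis=0), m2=x.T @ x, x=x,
            ))
    if not groups:
        raise ValueError("no families with observed phenotypes")
    return groups


def _data_fingerprint(groups: list[_PatternGroup]) -> tuple:
    n = sum(g.n for g in groups)
    total = float(sum(g.s.sum() for g in groups))
    ss = float(sum(np.trace(g.m2) for g in groups))
    return (n, round(total, 8), round(ss, 8))


# ---------------------------------------------------------------------------
# implied moments and FIML objective
# ---------------------------------------------------------------------------

def implied_covariance(params: CholeskyParams, spec: ModelSpec, zygosity: str):
    """Model-implied 6x6 covariance and 6-vector of means for one zygosity.

    Within-twin blocks are ``A + C + E``; the cross-twin block is
    ``alpha * A + C`` with alpha = 1 for MZ and ``spec.dz_alpha`` for DZ.
    The result is exactly symmetric and positive semi-definite for any
    parameter values (Cholesky construction).
    """
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    alpha = 1.0 if zygosity == "MZ" else spec.dz_alpha
    A = params.component("A")
    C = params.component("C") if spec.has_c else np.zeros((3, 3))
    E = params.component("E")
    S = A + C + E
    B = alpha * A + C
    sigma = np.block([[S, B], [B.T, S]])
    sigma = (sigma + sigma.T) / 2.0
    mu6 = np.concatenate([params.mu, params.mu])
    return sigma, mu6


def _nll_grad(theta: np.ndarray, spec: ModelSpec, groups: list[_PatternGroup]):
    """-2 log likelihood and its analytic gradient in the theta packing.

    Returns a large finite penalty (gradient zero) when an implied observed
    covariance is numerically singular, so line searches can back off.
    """
    params = CholeskyParams.from_vector(theta, spec)
    sigma = {z: implied_covariance(params, spec, z)[0] for z in ("MZ", "DZ")}
    mu6 = np.concatenate([params.mu, params.mu])

    nll = 0.0
    ghat = {"MZ": np.zeros((6, 6)), "DZ": np.zeros((6, 6))}  # d nll / d Sigma_z
    gmu6 = np.zeros(6)
    for g in groups:
        k = g.obs.size
        sub = sigma[g.zygosity][np.ix_(g.obs, g.obs)]
        try:
            cf = linalg.cho_factor(sub, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return _PENALTY, np.zeros_like(theta)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        if not np.isfinite(logdet):
            return _PENALTY, np.zeros_like(theta)
        W = linalg.cho_solve(cf, np.eye(k), check_finite=False)
        muo = mu6[g.obs]
        # sum_i r_i r_i' from sufficient statistics
        m2c = g.m2 - np.outer(g.s, muo) - np.outer(muo, g.s) + g.n * np.outer(muo, muo)
        nll += g.n * (k * _LN2PI + logdet) + float(np.sum(W * m2c))
        G = g.n * W - W @ m2c @ W
        ghat[g.zygosity][np.ix_(g.obs, g.obs)] += G
        gmu6[g.obs] += -2.0 * (W @ (g.s - g.n * muo))

    # fold 6x6 Sigma-gradients into 3x3 component gradients
    gA = np.zeros((3, 3))
    gC = np.zeros((3, 3))
    gE = np.zeros((3, 3))
    for zyg, alpha in (("MZ", 1.0), ("DZ", spec.dz_alpha)):
        H = ghat[zyg]
        diag = H[:3, :3] + H[3:, 3:]
        cross = H[:3, 3:] + H[3:, :3]
        gA += diag + alpha * cross
        gC += diag + cross
        gE += diag

    parts = [(2.0 * gA @ params.L_A)[_TRIL]]
    if spec.has_c:
        parts.append((2.0 * gC @ params.L_C)[_TRIL])
    parts.append((2.0 * gE @ params.L_E)[_TRIL])
    parts.append(gmu6[:3] + gmu6[3:])
    return nll, np.concatenate(parts)


def neg2_log_likelihood(params: CholeskyParams, spec: ModelSpec, data) -> float:
    """-2 log likelihood of a phenotype table (or prepared groups) under the
    implied multivariate-normal structure, summed over families.

    Each family contributes ``k ln 2pi + ln|Sigma_obs| + r' Sigma_obs^-1 r``
    over its observed entries. A singular implied covariance yields a large
    finite penalty rather than an exception.
    """
    groups = data if isinstance(data, list) else family_groups(data)
    value, _ = _nll_grad(params.to_vector(spec), spec, groups)
    return float(value)


# ---------------------------------------------------------------------------
# start values
# ---------------------------------------------------------------------------

def falconer_estimates(rMZ, rDZ, clip: bool = False):
    """Falconer moment estimates per trait from MZ/DZ twin correlations.

    ``a2 = 2(rMZ - rDZ)``, ``c2 = 2 rDZ - rMZ``, ``e2 = 1 - rMZ``. With
    ``clip=True`` the shares are clipped to [0, 1] and renormalized to sum
    to 1 — the form used for optimizer start values.
    """
    rMZ = np.asarray(rMZ, float)
    rDZ = np.asarray(rDZ, float)
    a2 = 2.0 * (rMZ - rDZ)
    c2 = 2.0 * rDZ - rMZ
    e2 = 1.0 - rMZ
    if clip:
        a2, c2, e2 = (np.clip(v, 0.0, 1.0) for v in (a2, c2, e2))
        total = a2 + c2 + e2
        total = np.where(total <= 0, 1.0, total)
        a2, c2, e2 = a2 / total, c2 / total, e2 / total
    return a2, c2, e2


def _safe_cholesky(M: np.ndarray) -> np.ndarray:
    M = (M + M.T) / 2.0
    for eps in (0.0, 1e-8, 1e-4, 1e-2):
        try:
            return np.linalg.cholesky(M + eps * np.eye(3))
        except np.linalg.LinAlgError:
            continue
    return np.diag(np.sqrt(np.clip(np.diag(M), 1e-6, None)))


def _auto_start(table: pd.DataFrame, spec: ModelSpec) -> CholeskyParams:
    """Start values from Falconer estimates on double-entry correlations."""
    ind = td.individual_table(table)
    vals = ind[list(TRAITS)].to_numpy(float)
    mu = np.nanmean(vals, axis=0)
    var = np.nanvar(vals, axis=0, ddof=1)
    var = np.where(np.isfinite(var) & (var > 0), var, 1.0)
    rph = td.phenotypic_correlations(table).to_numpy()
    rph = np.where(np.isfinite(rph), rph, 0.0)
    np.fill_diagonal(rph, 1.0)

    rMZ, rDZ = np.full(3, 0.3), np.full(3, 0.15)
    for i, trait in enumerate(TRAITS):
        for zyg, arr in (("MZ", rMZ), ("DZ", rDZ)):
            try:
                r = td.icc(td.pair_values(table, trait, zyg))
                if np.isfinite(r):
                    arr[i] = r
            except ValueError:
                pass
    a2, c2, e2 = falconer_estimates(rMZ, rDZ, clip=True)
    a2 = np.clip(a2, 0.05, 0.90)
    if spec.has_c:
        c2 = np.clip(c2, 0.05, 0.90)
    else:
        c2 = np.zeros(3)
    e2 = np.clip(1.0 - a2 - c2, 0.10, None)
    total = a2 + c2 + e2
    a2, c2, e2 = a2 / total, c2 / total, e2 / total

    def comp(shares):
        d = np.sqrt(shares * var)
        return np.outer(d, d) * rph

    params = CholeskyParams(
        L_A=_safe_cholesky(comp(a2)),
        L_E=_safe_cholesky(comp(e2)),
        mu=mu,
        L_C=_safe_cholesky(comp(c2)) if spec.has_c else None,
    )
    return params


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fix_signs(params: CholeskyParams) -> CholeskyParams:
    """Flip Cholesky columns so diagonals are non-negative (likelihood-
    invariant: A = L L' is unchanged by column sign flips)."""
    def fix(L):
        if L is None:
            return None
        L = L.copy()
        for k in range(3):
            if L[k, k] < 0:
                L[:, k] *= -1.0
        return L

    return replace(params, L_A=fix(params.L_A), L_C=fix(params.L_C), L_E=fix(params.L_E))


def fit_model(
    table: pd.DataFrame,
    spec: ModelSpec | str = "AE",
    start: CholeskyParams | str = "auto",
    *,
    n_restarts: int = 5,
    maxiter: int = 2000,
    gtol: float = 1e-5,
    jitter_seed: int = 0,
) -> FitResult:
    """Fit the trivariate ACE or AE Cholesky model by FIML.

    Parameters
    ----------
    table
        Family-wide phenotype table (``t1_*``/``t2_*`` columns); incomplete
        families and singletons contribute their observed entries only.
    spec
        ``ModelSpec`` or a variant name ("ACE"/"AE").
    start
        "auto" (Falconer-based start derived from double-entry twin
        correlations) or explicit :class:`CholeskyParams`.
    n_restarts
        Jittered restarts attempted when the first minimization does not
        converge; the best minimum found is kept.
    gtol
        Convergence requires the gradient norm, scaled by max(1, |-2lnL|),
        to fall below this.

    Raises
    ------
    ValueError
        If either zygosity group contributes no observed data (A and C are
        then not separable from the MZ/DZ contrast).
    """
    if isinstance(spec, str):
        spec = ModelSpec(variant=spec)
    groups = family_groups(table)
    zygs = {g.zygosity for g in groups}
    if zygs != {"MZ", "DZ"}:
        missing = {"MZ", "DZ"} - zygs
        raise ValueError(
            f"no {'/'.join(sorted(missing))} families with observed data; "
            "both zygosity groups are required to identify the model"
        )

    theta0 = (start if isinstance(start, CholeskyParams) else _auto_start(table, spec)).to_vector(spec)
    rng = np.random.default_rng(jitter_seed)

    best = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            t0 = theta0
        else:
            scale = np.maximum(np.abs(theta0), 0.1)
            t0 = theta0 + rng.normal(0.0, 0.1, size=theta0.size) * scale
        res = optimize.minimize(
            _nll_grad, t0, args=(spec, groups), jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8, "maxcor": 25},
        )
        gnorm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.inf
        ok = bool(np.isfinite(res.fun)) and gnorm / max(1.0, abs(res.fun)) < gtol
        if best is None or res.fun < best[0].fun - 1e-10:
            best = (res, gnorm, ok)
        if ok and res.fun <= best[0].fun + 1e-8:
            best = (res, gnorm, ok)
            break
    res, gnorm, ok = best

    params = _fix_signs(CholeskyParams.from_vector(res.x, spec))
    patterns = {}
    for g in groups:
        key = f"{g.zygosity}:{len(g.obs)}obs"
        patterns[key] = patterns.get(key, 0) + g.n
    return FitResult(
        params=params,
        spec=spec,
        minus2LL=float(res.fun),
        n_params=spec.n_params,
        converged=ok,
        n_iter=int(res.nit),
        grad_norm=gnorm,
        data_summary={
            "n_families": int(sum(g.n for g in groups)),
            "patterns": patterns,
            "fingerprint": _data_fingerprint(groups),
        },
    )


# ---------------------------------------------------------------------------
# standardization and model comparison
# ---------------------------------------------------------------------------

def _corr_from_cov(M: np.ndarray) -> np.ndarray:
    d = np.diag(M).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(d, d))
        R = np.where(denom > 0, M / denom, np.nan)
    return R


def standardize(params: CholeskyParams, spec: ModelSpec) -> CorrelatedFactorsSolution:
    """Correlated-factors solution of a fitted Cholesky parameterization.

    ``a2_i = A_ii / S_ii`` (likewise c2, e2), ``rA_ij = A_ij / sqrt(A_ii
    A_jj)`` (likewise rC, rE), and ``contrib_A_ij = A_ij / sqrt(S_ii S_jj) =
    sqrt(a2_i) rA_ij sqrt(a2_j)`` — the share of the phenotypic correlation
    carried by A. Correlations of a component with zero variance are NaN;
    sampling-inflated correlations above 1 are reported as computed.
    """
    A = params.component("A")
    C = params.component("C") if spec.has_c else np.zeros((3, 3))
    E = params.component("E")
    S = A + C + E
    dS = np.diag(S)
    with np.errstate(invalid="ignore", divide="ignore"):
        a2 = np.where(dS > 0, np.diag(A) / dS, np.nan)
        c2 = np.where(dS > 0, np.diag(C) / dS, np.nan)
        e2 = np.where(dS > 0, np.diag(E) / dS, np.nan)
        denomS = np.sqrt(np.outer(dS, dS))
        contrib = lambda M: np.where(denomS > 0, M / denomS, np.nan)
    return CorrelatedFactorsSolution(
        a2=a2, c2=c2, e2=e2,
        rA=_corr_from_cov(A), rC=_corr_from_cov(C), rE=_corr_from_cov(E),
        r_phenotypic=_corr_from_cov(S),
        contrib_A=contrib(A), contrib_C=contrib(C), contrib_E=contrib(E),
    )


def compare_models(fit_full: FitResult, fit_reduced: FitResult) -> dict:
    """Likelihood-ratio and AIC comparison of nested ACE vs AE fits.

    ``chi2 = -2lnL(AE) - (-2lnL(ACE))`` on 6 df (the dropped C loadings);
    no boundary mixture correction is applied to the chi-square reference.
    Raises if the fits are not an ACE/AE pair on identical data.
    """
    if fit_full.spec.variant != "ACE" or fit_reduced.spec.variant != "AE":
        raise ValueError("expected fit_full=ACE and fit_reduced=AE")
    fp_full = fit_full.data_summary.get("fingerprint")
    fp_red = fit_reduced.data_summary.get("fingerprint")
    if fp_full != fp_red:
        raise ValueError("fits were produced from different data")
    df = fit_full.n_params - fit_reduced.n_params
    chi2 = fit_reduced.minus2LL - fit_full.minus2LL
    p = float(stats.chi2.sf(max(chi2, 0.0), df))
    return {
        "chi2": float(chi2),
        "df": int(df),
        "p": p,
        "delta_AIC": float(fit_reduced.AIC - fit_full.AIC),
    }


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

_SOLUTION_FIELDS = ("a2", "c2", "e2", "rA", "rC", "rE",
                    "r_phenotypic", "contrib_A", "contrib_C", "contrib_E")


def bootstrap_model_ci(
    table: pd.DataFrame,
    spec: ModelSpec | str = "AE",
    n_iter: int = 100,
    seed=None,
    level: float = 0.95,
    base_fit: FitResult | None = None,
) -> tuple[FitResult, CorrelatedFactorsSolution]:
    """Percentile bootstrap CIs for every standardized quantity.

    Families are resampled with replacement stratified by zygosity; each
    resample is refitted starting from the full-data solution. Non-converged
    resamples are dropped and counted; more than 20% failures raises.

    Returns the full-data fit and its solution with ``cis`` populated:
    quantity name -> (lower, upper) arrays, plus ``boot_info`` (n_iter,
    n_failed, seed, level).
    """
    if isinstance(spec, str):
        spec = ModelSpec(variant=spec)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    fit = base_fit if base_fit is not None else fit_model(table, spec)
    solution = standardize(fit.params, spec)

    rng = np.random.default_rng(seed)
    groups = [g for _, g in table.groupby("zygosity", sort=True)]
    draws = {f: [] for f in _SOLUTION_FIELDS}
    n_failed = 0
    for _ in range(n_iter):
        parts = [g.sample(n=len(g), replace=True, random_state=rng) for g in groups]
        resample = pd.concat(parts, ignore_index=True)
        try:
            refit = fit_model(resample, spec, start=fit.params, n_restarts=2,
                              jitter_seed=int(rng.integers(2**31 - 1)))
        except ValueError:
            n_failed += 1
            continue
        if not refit.converged:
            n_failed += 1
            continue
        sol = standardize(refit.params, spec)
        for f in _SOLUTION_FIELDS:
            draws[f].append(getattr(sol, f))
    if n_failed > 0.2 * n_iter:
        raise RuntimeError(
            f"{n_failed}/{n_iter} bootstrap resamples failed to converge"
        )
    alpha = (1.0 - level) / 2.0
    cis = {}
    for f in _SOLUTION_FIELDS:
        stacked = np.stack(draws[f])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices (e.g. rC in AE)
            lo = np.nanpercentile(stacked, 100 * alpha, axis=0)
            hi = np.nanpercentile(stacked, 100 * (1 - alpha), axis=0)
        cis[f] = (lo, hi)
    solution.cis = cis
    solution.boot_info = {"n_iter": n_iter, "n_failed": n_failed,
                          "seed": seed, "level": level}
    return fit, solution
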