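"""Synthetic twin-family data with known ACE/AE structure.

Two levels of simulation:

* :func:`simulate_twin_phenotypes` draws family phenotype tables directly
  from the multivariate-normal structure a :class:`GeneratingModel` implies —
  the generative counterpart of the biometric model, used for parameter
  recovery and calibration checks.
* :func:`simulate_trial_level` emits trial-by-trial expectancy ratings (and a
  participant roster) whose window-mean differentials track each
  participant's latent phenotypes, exercising the full phenotype-derivation
  pipeline including rating discretization, pseudo-randomized trial order and
  75% reinforcement.

:func:`paper_generating_model` encodes the published point estimates for the
three fear-conditioning phenotypes — an AE model with heritabilities
(0.15, 0.29, 0.15), genetic correlations (0.99, 0.42, 0.44) and non-shared
environment correlations (0.49, 0.31, 0.41) — at the study's sample plan of
250 MZ pairs, 288 DZ pairs and 860 singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trial_phenotypes import TRAITS, PHENOTYPE_COLUMNS
from .biometric_model import CholeskyParams, ModelSpec, implied_covariance

__all__ = [
    "GeneratingModel",
    "SamplePlan",
    "TaskDesign",
    "paper_generating_model",
    "simulate_twin_phenotypes",
    "simulate_trial_level",
]


def _as_corr(M) -> np.ndarray:
    M = np.asarray(M, float)
    if M.shape != (3, 3):
        raise ValueError("correlation matrices must be 3x3")
    if not np.allclose(M, M.T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(M), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.any(np.abs(M) > 1.0 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    return M


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-10) -> None:
    w = np.linalg.eigvalsh((M + M.T) / 2.0)
    if w.min() < -tol:
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g})")


@dataclass(frozen=True)
class SamplePlan:
    """Family counts drawn by the generator.

    Singletons carry a zygosity label (their co-twin simply did not provide
    data); the default split is proportional to the MZ:DZ pair ratio.
    """

    n_mz_pairs: int = 250
    n_dz_pairs: int = 288
    n_mz_singletons: int = 400
    n_dz_singletons: int = 460

    @property
    def n_singletons(self) -> int:
        return self.n_mz_singletons + self.n_dz_singletons

    @property
    def n_individuals(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs) + self.n_singletons


@dataclass(frozen=True)
class GeneratingModel:
    """Ground-truth standardized ACE/AE structure for simulation.

    ``a2 + c2 + e2 = 1`` per trait; total trait variances default to 1 and
    means to 0 (the analysed phenotypes are residualized and transformed, so
    their scale is arbitrary). Implied 6x6 covariances for both zygosities
    are checked positive semi-definite at construction.
    """

    variant: str = "AE"
    a2: tuple = (0.15, 0.29, 0.15)
    c2: tuple = (0.0, 0.0, 0.0)
    rA: np.ndarray = field(default_factory=lambda: np.eye(3))
    rC: np.ndarray = field(default_factory=lambda: np.eye(3))
    rE: np.ndarray = field(default_factory=lambda: np.eye(3))
    means: tuple = (0.0, 0.0, 0.0)
    variances: tuple = (1.0, 1.0, 1.0)
    plan: SamplePlan = field(default_factory=SamplePlan)

    def __post_init__(self):
        if self.variant not in ("ACE", "AE"):
            raise ValueError(f"unknown variant {self.variant!r}")
        a2 = np.asarray(self.a2, float)
        c2 = np.asarray(self.c2, float)
        if self.variant == "AE" and np.any(c2 != 0):
            raise ValueError("AE generating model requires c2 = 0")
        if np.any(a2 < 0) or np.any(c2 < 0) or np.any(a2 + c2 > 1 + 1e-12):
            raise ValueError("a2, c2 must be non-negative with a2 + c2 <= 1")
        for name in ("rA", "rC", "rE"):
            object.__setattr__(self, name, _as_corr(getattr(self, name)))
            _check_psd(getattr(self, name), name)
        if np.any(np.asarray(self.variances, float) <= 0):
            raise ValueError("variances must be positive")
        for zyg in ("MZ", "DZ"):
            _check_psd(self.implied_covariance(zyg)[0], f"implied {zyg} covariance")

    @property
    def e2(self) -> np.ndarray:
        return 1.0 - np.asarray(self.a2, float) - np.asarray(self.c2, float)

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(variant=self.variant)

    def components(self):
        """Component covariance matrices (A, C, E) on the trait scale."""
        var = np.asarray(self.variances, float)

        def comp(share, R):
            d = np.sqrt(np.asarray(share, float) * var)
            return np.outer(d, d) * R

        return comp(self.a2, self.rA), comp(self.c2, self.rC), comp(self.e2, self.rE)

    def params(self) -> CholeskyParams:
        """Ground truth expressed as (generalized) Cholesky loadings.

        Uses an eigenvalue factorization F with F F' = M, which tolerates
        exactly singular components (e.g. e2 = 0); the implied covariance
        only depends on F F', so lower-triangularity is not required here.
        """
        A, C, E = self.components()

        def chol(M):
            w, V = np.linalg.eigh((M + M.T) / 2.0)
            return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

        L_A, L_C, L_E = (chol(M) for M in (A, C, E))
        return CholeskyParams(
            L_A=L_A, L_E=L_E, mu=np.asarray(self.means, float),
            L_C=L_C if self.variant == "ACE" else None,
        )

    def implied_covariance(self, zygosity: str):
        """Implied 6x6 covariance and mean vector for one zygosity."""
        A, C, E = self.components()
        alpha = 1.0 if zygosity == "MZ" else 0.5
        S = A + C + E
        B = alpha * A + C
        sigma = np.block([[S, B], [B, S]])
        mu = np.concatenate([self.means, self.means])
        return (sigma + sigma.T) / 2.0, mu

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("rA", "rC", "rE"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def paper_generating_model(plan: SamplePlan | None = None) -> GeneratingModel:
    """AE generating model at the published point estimates.

    Heritabilities a2 = (0.15, 0.29, 0.15) for initial development,
    consolidation and extinction; genetic correlations rA(1,2) = 0.99,
    rA(1,3) = 0.42, rA(2,3) = 0.44; non-shared environment correlations
    rE = (0.49, 0.31, 0.41) pairwise (the publication prints rE only as
    ranges; this assignment is the package default and is configurable by
    constructing a :class:`GeneratingModel` directly). Sample plan: 250 MZ
    pairs, 288 DZ pairs, 860 singletons.
    """
    rA = np.array([[1.0, 0.99, 0.42],
                   [0.99, 1.0, 0.44],
                   [0.42, 0.44, 1.0]])
    rE = np.array([[1.0, 0.49, 0.31],
                   [0.49, 1.0, 0.41],
                   [0.31, 0.41, 1.0]])
    return GeneratingModel(
        variant="AE",
        a2=(0.15, 0.29, 0.15),
        rA=rA,
        rE=rE,
        plan=plan if plan is not None else SamplePlan(),
    )


# ---------------------------------------------------------------------------
# phenotype-level simulation
# ---------------------------------------------------------------------------

_SECTION_KEYS = {"MZ_pairs": 11, "DZ_pairs": 13, "MZ_singles": 17, "DZ_singles": 19}


def _stream(seed, label: str) -> np.random.Generator:
    """Independent, extensible stream per sample-plan section.

    Each section (MZ pairs, DZ pairs, singletons per zygosity) draws from its
    own child stream in family order, so enlarging one section's count leaves
    every family already drawn — in any section — unchanged.
    """
    ss = np.random.SeedSequence([int(seed), _SECTION_KEYS[label]])
    return np.random.default_rng(ss)


def simulate_twin_phenotypes(model: GeneratingModel, seed) -> pd.DataFrame:
    """Draw a family-wide phenotype table from the generating model.

    Complete pairs are 6-variate normal draws under the zygosity-appropriate
    implied covariance; singletons are drawn from the 3-variate within-twin
    margin. Reproducible under the seed; the table carries
    ``attrs["stage"] = "normalized"`` (phenotypes are generated directly on
    the analysis scale).
    """
    rows = []

    def draw_block(label, n, sigma, mu):
        if n == 0:
            return np.empty((0, len(mu)))
        rng = _stream(seed, label)
        # eigendecomposition factor tolerates exactly singular covariances
        # (e.g. e2 = 0 makes MZ co-twins identical to machine precision)
        w, V = np.linalg.eigh(sigma)
        F = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        z = rng.standard_normal((n, len(mu)))
        return mu + z @ F.T

    for zyg in ("MZ", "DZ"):
        sigma, mu6 = model.implied_covariance(zyg)
        n_pairs = model.plan.n_mz_pairs if zyg == "MZ" else model.plan.n_dz_pairs
        block = draw_block(f"{zyg}_pairs", n_pairs, sigma, mu6)
        for i, vals in enumerate(block):
            row = {"family_id": f"{zyg}P{i + 1:05d}", "zygosity": zyg}
            for j, t in enumerate(TRAITS):
                row[f"t1_{t}"] = vals[j]
                row[f"t2_{t}"] = vals[3 + j]
            rows.append(row)

        n_single = model.plan.n_mz_singletons if zyg == "MZ" else model.plan.n_dz_singletons
        sigma3 = sigma[:3, :3]
        block = draw_block(f"{zyg}_singles", n_single, sigma3, mu6[:3])
        for i, vals in enumerate(block):
            row = {"family_id": f"{zyg}S{i + 1:05d}", "zygosity": zyg}
            for j, t in enumerate(TRAITS):
                row[f"t1_{t}"] = vals[j]
                row[f"t2_{t}"] = np.nan
            rows.append(row)

    table = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    table.attrs["stage"] = "normalized"
    return table


# ---------------------------------------------------------------------------
# trial-level simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Design constants of the fear-conditioning task.

    12 presentations per stimulus in acquisition with the CS+ reinforced on
    exactly 9 (75%), 18 unreinforced presentations per stimulus in
    extinction, ratings on a 1-9 expectancy scale, and a pseudo-randomized
    stimulus order with at most 2 identical consecutive presentations.
    """

    acquisition_trials: int = 12
    reinforced_trials: int = 9
    extinction_trials: int = 18
    rating_min: int = 1
    rating_max: int = 9
    max_consecutive: int = 2

    def __post_init__(self):
        if self.reinforced_trials > self.acquisition_trials:
            raise ValueError("reinforced_trials cannot exceed acquisition_trials")
        if self.rating_min >= self.rating_max:
            raise ValueError("rating bounds must be ordered")
        # cap-1 with equal counts alternates; any cap >= 1 with equal counts feasible,
        # but reject infeasible caps for the interleaved two-stimulus sequence
        if self.max_consecutive < 1:
            raise ValueError("max_consecutive must be >= 1")


@dataclass(frozen=True)
class TrialNoise:
    """Observation model mapping latent differentials to ratings.

    Latent phenotypes (standard normal) are placed on the raw differential
    scale via ``target = mean + sd * z``; individual ratings add Gaussian
    noise before rounding and clipping to the 1-9 scale. Default window
    means follow the published descriptives (initial-development CS+ 6.05 vs
    CS- 3.70, i.e. a mean differential of 2.35, growing by consolidation and
    partly extinguishing); differential s.d.s near 2 are implied by
    per-stimulus s.d.s of ~1.6 under modest CS+/CS- correlation. Defaults
    give round-trip correlations above 0.9 between latent and derived
    phenotypes.
    """

    target_means: tuple = (2.35, 4.5, 2.0)   # initial, consol, extinct (raw diff scale)
    target_sds: tuple = (2.0, 2.0, 1.8)
    rating_sd: float = 0.7
    age_slope: float = 0.0    # optional age effect injected on the raw scale
    sex_effect: float = 0.0   # optional M-F offset on the raw scale


def _stimulus_order(n_per_stim: int, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random interleaving of two stimuli, at most `cap` identical in
    a row. 1 = CS+, 0 = CS-."""
    if n_per_stim > cap * (n_per_stim + 1):
        raise ValueError("infeasible pseudo-randomization constraint")
    seq = np.array([1] * n_per_stim + [0] * n_per_stim)
    for _ in range(1000):
        rng.shuffle(seq)
        runs = np.diff(np.flatnonzero(np.concatenate(([True], np.diff(seq) != 0, [True]))))
        if runs.max() <= cap:
            return seq.copy()
    # constructive fallback: alternate blocks
    return np.tile([1, 0], n_per_stim)


def _phase_trajectory(n: int, shape: str) -> np.ndarray:
    """Unit-free differential trajectory over trials of one phase."""
    t = np.arange(1, n + 1)
    if shape == "rise":       # logistic rise across acquisition
        return 1.0 / (1.0 + np.exp(-(t - n / 3.0) / (n / 8.0)))
    if shape == "decay":      # exponential decay across extinction
        return np.exp(-(t - 1) / (n / 3.0))
    raise ValueError(shape)


def _acquisition_differentials(d_init: float, d_consol: float, n: int) -> np.ndarray:
    """Per-trial differential whose means over trials 1..n/3 and 2n/3+1..n
    equal the two targets exactly (affine anchoring of a logistic shape)."""
    s = _phase_trajectory(n, "rise")
    third = n // 3
    m1, m2 = s[:third].mean(), s[-third:].mean()
    if abs(m2 - m1) < 1e-12:
        return np.full(n, (d_init + d_consol) / 2.0)
    b = (d_consol - d_init) / (m2 - m1)
    a = d_init - b * m1
    return a + b * s


def _extinction_differentials(d_ext: float, n: int) -> np.ndarray:
    """Decaying differential whose mean over the first third equals the target."""
    s = _phase_trajectory(n, "decay")
    third = n // 3
    return d_ext / s[:third].mean() * s


def simulate_trial_level(
    model: GeneratingModel,
    design: TaskDesign | None = None,
    seed=0,
    noise: TrialNoise | None = None,
):
    """Emit trial-level ratings and a participant roster from latent
    phenotypes drawn under the generating model.

    Each participant's latent 3-vector (from
    :func:`simulate_twin_phenotypes`) is mapped to raw differential targets;
    CS+ and CS- rating trajectories are built around a common expectancy
    level so that window-mean differentials reproduce the targets before
    rating noise, rounding and clipping. The CS+ is reinforced on exactly 9
    of 12 acquisition trials; stimulus order respects the
    maximum-2-consecutive rule. Ages are drawn uniform on 22-25.5 years
    (shared within pair), sexes F/M with MZ/DZ same-sex pairs sharing sex and
    a fraction of DZ pairs opposite-sex. Exclusion flags are all false.

    Returns ``(trials, roster)`` DataFrames in the CSV dialects consumed by
    :mod:`twinfear.trial_phenotypes`.
    """
    design = design or TaskDesign()
    noise = noise or TrialNoise()
    latent = simulate_twin_phenotypes(model, seed)

    # participant-level roster from family rows
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    participants = []  # (pid, family_id, zygosity, sex, age, latent z-vector)
    for _, fam in latent.iterrows():
        age = float(rng.uniform(22.0, 25.5))
        opposite = fam["zygosity"] == "DZ" and rng.random() < 107.0 / 288.0
        sex1 = "F" if rng.random() < 0.6 else "M"
        sex2 = ("M" if sex1 == "F" else "F") if opposite else sex1
        members = [("1", sex1), ("2", sex2)]
        for k, sex in members:
            z = np.array([fam[f"t{k}_{t}"] for t in TRAITS], float)
            if np.isnan(z).all():
                continue
            participants.append((f"{fam['family_id']}-{k}", fam["family_id"],
                                 fam["zygosity"], sex, age, z))

    roster = pd.DataFrame(
        [{"participant_id": pid, "family_id": fid, "zygosity": zyg, "sex": sex,
          "age": age, "excluded_headphones": 0, "excluded_volume": 0,
          "excluded_exit": 0}
         for pid, fid, zyg, sex, age, _ in participants]
    )

    n_acq, n_ext = design.acquisition_trials, design.extinction_trials
    lo, hi = design.rating_min, design.rating_max
    means = np.asarray(noise.target_means, float)
    sds = np.asarray(noise.target_sds, float)

    records = []
    for p_idx, (pid, fid, zyg, sex, age, z) in enumerate(participants):
        prng = np.random.default_rng(np.random.SeedSequence([int(seed), 29, p_idx]))
        # presentation order per phase (validates the pseudo-randomization
        # constraint; the emitted dialect keys on per-stimulus trial_index)
        _stimulus_order(n_acq, design.max_consecutive, prng)
        _stimulus_order(n_ext, design.max_consecutive, prng)
        targets = means + sds * z
        targets += noise.age_slope * (age - 23.75)
        targets += noise.sex_effect * (1.0 if sex == "M" else 0.0)
        max_d = float(hi - lo)
        targets = np.clip(targets, -max_d, max_d)

        d_acq = _acquisition_differentials(targets[0], targets[1], n_acq)
        d_ext = _extinction_differentials(targets[2], n_ext)
        # common expectancy level: mid-scale during acquisition, decaying in
        # extinction; shifted per trial so c +/- d/2 stays on the 1-9 scale
        # (otherwise ceiling clipping would attenuate large differentials)
        c_acq = np.full(n_acq, (lo + hi) / 2.0 - 0.1)
        c_ext = (lo + hi) / 2.0 * _phase_trajectory(n_ext, "decay") + lo
        c_acq = np.clip(c_acq, lo + np.abs(d_acq) / 2.0, hi - np.abs(d_acq) / 2.0)
        c_ext = np.clip(c_ext, lo + np.abs(d_ext) / 2.0, hi - np.abs(d_ext) / 2.0)

        reinf_slots = np.zeros(n_acq, bool)
        reinf_slots[prng.choice(n_acq, design.reinforced_trials, replace=False)] = True

        for phase, n_trials, c_level, d_level in (
            ("acquisition", n_acq, c_acq, d_acq),
            ("extinction", n_ext, c_ext, d_ext),
        ):
            for stim, sign in (("CS_plus", +0.5), ("CS_minus", -0.5)):
                vals = c_level + sign * d_level + prng.normal(0, noise.rating_sd, n_trials)
                ratings = np.clip(np.rint(vals), lo, hi).astype(int)
                for idx in range(n_trials):
                    reinforced = int(
                        phase == "acquisition" and stim == "CS_plus" and reinf_slots[idx]
                    )
                    records.append((pid, phase, stim, idx + 1, ratings[idx], reinforced))

    trials = pd.DataFrame(
        records,
        columns=["participant_id", "phase", "stimulus", "trial_index", "rating", "reinforced"],
    )
    # interleaved presentation order (metadata only; analyses key on trial_index)
    return trials, roster
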