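"""Derivation of differential fear-conditioning phenotypes from trial-level data.

A remote fear-conditioning task presents two conditional stimuli (CS+ and CS-)
over an acquisition phase (12 trials per stimulus, the CS+ reinforced with an
aversive noise on 9 of 12 presentations) and an extinction phase (18 trials per
stimulus, no reinforcement). On every trial the participant rates how much they
expect the aversive outcome on a 1-9 scale.

Three phenotypes index discriminative learning as CS+ minus CS- window means:

* ``initial`` — first third of acquisition (trials 1-4 per stimulus),
* ``consol`` — last third of acquisition (trials 9-12 per stimulus),
* ``extinct`` — first third of extinction (trials 1-6 per stimulus).

Before twin modelling the scores are residualized on age and sex (to avoid
inflating twin correlations through cohort effects) and passed through a signed
square-root transform. The late-extinction window exists for descriptives but
is not carried into modelling: by then nearly all participants rate both
stimuli at floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "PHASE_TRIALS",
    "WINDOW_TRIALS",
    "ExclusionReport",
    "load_trial_data",
    "apply_exclusions",
    "compute_differential",
    "residualize_age_sex",
    "normalize_sqrt",
    "derive_phenotypes",
    "read_phenotypes",
    "write_phenotypes",
]

#: Modelled phenotypes, in fixed order (columns of every downstream matrix).
TRAITS = ("initial", "consol", "extinct")

#: Trials per stimulus in each phase.
PHASE_TRIALS = {"acquisition": 12, "extinction": 18}

#: (phase, window) -> inclusive 1-based trial range per stimulus.
WINDOW_TRIALS = {
    ("acquisition", "first_third"): (1, 4),
    ("acquisition", "last_third"): (9, 12),
    ("extinction", "first_third"): (1, 6),
    ("extinction", "last_third"): (13, 18),
}

#: (phase, window) pairs defining the three modelled phenotypes, in TRAITS order.
TRAIT_WINDOWS = {
    "initial": ("acquisition", "first_third"),
    "consol": ("acquisition", "last_third"),
    "extinct": ("extinction", "first_third"),
}

_TRIAL_COLUMNS = [
    "participant_id",
    "phase",
    "stimulus",
    "trial_index",
    "rating",
    "reinforced",
]
_ROSTER_COLUMNS = [
    "participant_id",
    "family_id",
    "zygosity",
    "sex",
    "age",
    "excluded_headphones",
    "excluded_volume",
    "excluded_exit",
]
_EXCLUSION_FLAGS = ["excluded_headphones", "excluded_volume", "excluded_exit"]

#: Wide phenotype-table columns (one row per family, twins 1 and 2).
PHENOTYPE_COLUMNS = [
    "family_id",
    "zygosity",
    "t1_initial",
    "t1_consol",
    "t1_extinct",
    "t2_initial",
    "t2_consol",
    "t2_extinct",
]


@dataclass
class ExclusionReport:
    """Tally of participants removed by task-compliance exclusions.

    Reasons are not mutually exclusive: a participant with several flags is
    removed once but counted under every applicable reason.
    """

    n_total: int
    n_retained: int
    n_removed: int
    by_reason: dict = field(default_factory=dict)


def load_trial_data(trial_file, participant_file):
    """Read and validate trial-level ratings and the participant roster.

    Parameters
    ----------
    trial_file
        CSV with columns ``participant_id, phase, stimulus, trial_index,
        rating, reinforced`` (reinforced coded 0/1).
    participant_file
        CSV with columns ``participant_id, family_id, zygosity, sex, age,
        excluded_headphones, excluded_volume, excluded_exit``.

    Returns
    -------
    (trials, roster) : tuple of DataFrame
        Validated trial records and participant roster. Trials whose
        participant is absent from the roster are dropped with a warning.

    Raises
    ------
    ValueError
        On ratings outside 1-9, unknown phase/stimulus codes, trial indices
        outside the phase design, reinforcement of anything but acquisition
        CS+, reinforcement counts other than 9 in a complete CS+ acquisition
        record, or duplicate (participant, phase, stimulus, trial) rows.
    """
    trials = pd.read_csv(trial_file, dtype={"participant_id": str})
    roster = pd.read_csv(participant_file, dtype={"participant_id": str, "family_id": str})
    missing = [c for c in _TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial file missing columns: {missing}")
    missing = [c for c in _ROSTER_COLUMNS if c not in roster.columns]
    if missing:
        raise ValueError(f"participant file missing columns: {missing}")

    _validate_roster(roster)
    trials = _validate_trials(trials)

    orphans = ~trials["participant_id"].isin(roster["participant_id"])
    if orphans.any():
        ids = sorted(trials.loc[orphans, "participant_id"].unique())
        warnings.warn(
            f"dropping {int(orphans.sum())} trials from {len(ids)} participants "
            f"absent from the roster (e.g. {ids[:3]})"
        )
        trials = trials.loc[~orphans].reset_index(drop=True)
    return trials, roster


def _validate_roster(roster: pd.DataFrame) -> None:
    if roster["participant_id"].duplicated().any():
        dups = roster.loc[roster["participant_id"].duplicated(), "participant_id"]
        raise ValueError(f"duplicate participant ids in roster: {sorted(dups)[:5]}")
    bad = ~roster["zygosity"].isin(["MZ", "DZ"])
    if bad.any():
        raise ValueError(f"unknown zygosity codes: {sorted(roster.loc[bad, 'zygosity'].unique())}")
    bad = ~roster["sex"].isin(["F", "M"])
    if bad.any():
        raise ValueError(f"unknown sex codes: {sorted(roster.loc[bad, 'sex'].unique())}")
    if (roster["age"] <= 0).any():
        raise ValueError("non-positive ages in roster")
    # family invariant: uniform zygosity within family
    nz = roster.groupby("family_id")["zygosity"].nunique()
    if (nz > 1).any():
        raise ValueError(f"families with mixed zygosity: {sorted(nz[nz > 1].index)[:5]}")


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    bad = ~trials["phase"].isin(PHASE_TRIALS)
    if bad.any():
        raise ValueError(f"unknown phase values: {sorted(trials.loc[bad, 'phase'].unique())}")
    bad = ~trials["stimulus"].isin(["CS_plus", "CS_minus"])
    if bad.any():
        raise ValueError(f"unknown stimulus values: {sorted(trials.loc[bad, 'stimulus'].unique())}")

    rating = trials["rating"]
    bad = ~(rating.between(1, 9) & (rating == rating.round()))
    if bad.any():
        rows = trials.index[bad].tolist()
        raise ValueError(f"ratings outside 1..9 at rows {rows[:5]} (0-based, first offending shown)")
    trials["rating"] = rating.astype(int)

    nmax = trials["phase"].map(PHASE_TRIALS)
    bad = ~(trials["trial_index"].between(1, nmax))
    if bad.any():
        raise ValueError(f"trial_index outside phase design at rows {trials.index[bad].tolist()[:5]}")

    trials["reinforced"] = trials["reinforced"].astype(int).astype(bool)
    bad = trials["reinforced"] & ~(
        (trials["phase"] == "acquisition") & (trials["stimulus"] == "CS_plus")
    )
    if bad.any():
        raise ValueError(
            f"reinforcement outside acquisition CS+ at rows {trials.index[bad].tolist()[:5]}"
        )

    keys = ["participant_id", "phase", "stimulus", "trial_index"]
    dup = trials.duplicated(subset=keys)
    if dup.any():
        raise ValueError(f"duplicate trial rows at {trials.index[dup].tolist()[:5]}")

    # complete CS+ acquisition records must carry exactly 9 reinforced trials
    acq = trials[(trials["phase"] == "acquisition") & (trials["stimulus"] == "CS_plus")]
    per = acq.groupby("participant_id")["reinforced"].agg(["count", "sum"])
    bad_ids = per.index[(per["count"] == 12) & (per["sum"] != 9)].tolist()
    if bad_ids:
        raise ValueError(
            f"complete CS+ acquisition records with reinforced count != 9: {bad_ids[:5]}"
        )
    return trials.reset_index(drop=True)


def apply_exclusions(trials: pd.DataFrame, roster: pd.DataFrame):
    """Drop all trials of participants flagged for any compliance exclusion.

    Participants are excluded if they removed their headphones, reduced
    phone volume below 50%, or exited the app during the task.

    Returns ``(trials_kept, roster_kept, report)``; removal is idempotent and
    an empty result is permitted.
    """
    flagged = roster[_EXCLUSION_FLAGS].astype(bool).any(axis=1)
    by_reason = {
        flag: int(roster[flag].astype(bool).sum()) for flag in _EXCLUSION_FLAGS
    }
    keep_ids = set(roster.loc[~flagged, "participant_id"])
    report = ExclusionReport(
        n_total=len(roster),
        n_retained=len(keep_ids),
        n_removed=int(flagged.sum()),
        by_reason=by_reason,
    )
    trials_kept = trials[trials["participant_id"].isin(keep_ids)].reset_index(drop=True)
    roster_kept = roster.loc[~flagged].reset_index(drop=True)
    return trials_kept, roster_kept, report


def compute_differential(trials: pd.DataFrame, phase: str, window: str) -> pd.Series:
    """CS+ minus CS- mean rating over a phase third, per participant.

    The window's mean for a stimulus requires at least half of its trials to
    be rated; otherwise the participant's score for this window is NaN (never
    an error). Scores are bounded in [-8, 8] and invariant to row order.
    """
    try:
        lo, hi = WINDOW_TRIALS[(phase, window)]
    except KeyError:
        raise ValueError(f"unknown phase/window combination: ({phase!r}, {window!r})") from None
    width = hi - lo + 1
    min_rated = width // 2 if width % 2 == 0 else (width + 1) // 2  # >= half

    sub = trials[(trials["phase"] == phase) & trials["trial_index"].between(lo, hi)]
    agg = sub.groupby(["participant_id", "stimulus"])["rating"].agg(["mean", "count"]).unstack()
    out = {}
    for pid in agg.index:
        row = agg.loc[pid]
        ok = all(
            (stim in agg["count"].columns) and row[("count", stim)] >= min_rated
            for stim in ("CS_plus", "CS_minus")
        )
        out[pid] = row[("mean", "CS_plus")] - row[("mean", "CS_minus")] if ok else np.nan
    return pd.Series(out, name=f"{phase}_{window}", dtype=float).rename_axis("participant_id")


def residualize_age_sex(scores: pd.Series, roster: pd.DataFrame) -> pd.Series:
    """Residualize a score on intercept + age + sex by ordinary least squares.

    Missing scores pass through as missing. With a degenerate design (uniform
    age and sex) the fit collapses to the intercept, returning centred scores.
    A zero-variance score triggers a warning and centred (all-zero) residuals.
    Residuals have mean zero and are orthogonal to age and the sex indicator
    within numerical tolerance; they are invariant to which sex is the
    reference level.
    """
    info = roster.set_index("participant_id")
    obs = scores.dropna()
    if len(obs) < 3:
        raise ValueError(f"need at least 3 non-missing scores, got {len(obs)}")
    y = obs.to_numpy(float)
    if np.ptp(y) == 0.0:
        warnings.warn("score has zero variance; returning centred scores")
        res = scores - y[0]
        return res.rename(scores.name)
    age = info.loc[obs.index, "age"].to_numpy(float)
    sex = (info.loc[obs.index, "sex"] == "M").to_numpy(float)
    X = np.column_stack([np.ones_like(y), age, sex])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)  # min-norm solution handles rank deficiency
    resid = y - X @ beta
    out = pd.Series(np.nan, index=scores.index, name=scores.name, dtype=float)
    out.loc[obs.index] = resid
    return out


def normalize_sqrt(x):
    """Signed square-root transform, sign(x)*sqrt(|x|).

    Defined on the whole line, odd, and strictly order-preserving; NaN passes
    through. Accepts scalars, arrays, or Series.
    """
    arr = np.asarray(x, dtype=float)
    result = np.sign(arr) * np.sqrt(np.abs(arr))
    if isinstance(x, pd.Series):
        return pd.Series(result, index=x.index, name=x.name)
    if np.isscalar(x):
        return float(result)
    return result


def derive_phenotypes(
    trials: pd.DataFrame,
    roster: pd.DataFrame,
    *,
    residualize: bool = True,
    transform: bool = True,
) -> pd.DataFrame:
    """Full pipeline from validated trials to the family-wide phenotype table.

    Applies exclusions, derives the three differential phenotypes, optionally
    residualizes on age/sex and applies the signed square-root, then pivots to
    one row per family (twin 1 = lexicographically first participant id).

    The result carries ``attrs["stage"]`` in {"raw", "residualized",
    "normalized"}; families where neither member has any phenotype are
    dropped.
    """
    trials, roster, _ = apply_exclusions(trials, roster)
    scores = pd.DataFrame(
        {t: compute_differential(trials, *TRAIT_WINDOWS[t]) for t in TRAITS}
    ).reindex(roster["participant_id"])
    stage = "raw"
    if residualize:
        scores = scores.apply(lambda col: residualize_age_sex(col, roster))
        stage = "residualized"
        if transform:
            scores = scores.apply(normalize_sqrt)
            stage = "normalized"

    info = roster.set_index("participant_id")
    rows = []
    for fam, members in info.groupby("family_id", sort=True):
        pids = sorted(members.index)
        if len(pids) > 2:
            raise ValueError(f"family {fam!r} has {len(pids)} members; at most 2 supported")
        row = {"family_id": fam, "zygosity": members["zygosity"].iloc[0]}
        for k, pid in enumerate(pids, start=1):
            for t in TRAITS:
                row[f"t{k}_{t}"] = scores.at[pid, t] if pid in scores.index else np.nan
        rows.append(row)
    table = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    value_cols = PHENOTYPE_COLUMNS[2:]
    table = table[table[value_cols].notna().any(axis=1)].reset_index(drop=True)
    table.attrs["stage"] = stage
    return table


def write_phenotypes(table: pd.DataFrame, path) -> None:
    """Write the family-wide phenotype table as CSV (empty cells = missing)."""
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_phenotypes(path, stage: str = "normalized") -> pd.DataFrame:
    """Read a phenotype CSV written by :func:`write_phenotypes`."""
    table = pd.read_csv(path, dtype={"family_id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    for col in PHENOTYPE_COLUMNS[2:]:
        table[col] = table[col].astype(float)
    table.attrs["stage"] = stage
    return table
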