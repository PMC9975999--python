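import numpy as np
import pandas as pd
import pytest

from twinfear import paper_generating_model
from twinfear.synthetic_data import SamplePlan


@pytest.fixture(scope="session")
def small_model():
    """Paper-structure generating model at a reduced sample plan."""
    return paper_generating_model(plan=SamplePlan(60, 60, 20, 20))


@pytest.fixture(scope="session")
def paper_model():
    return paper_generating_model()


def make_trials(participants, ratings=None, seed=0):
    """Complete-design trial table for the given participant ids.

    ratings: optional {(pid, phase, stimulus): list} override; defaults to a
    flat mid-scale rating of 5.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pid in participants:
        for phase, n in (("acquisition", 12), ("extinction", 18)):
            reinf_slots = set(rng.choice(n, 9, replace=False)) if phase == "acquisition" else set()
            for stim in ("CS_plus", "CS_minus"):
                vals = (ratings or {}).get((pid, phase, stim))
                for i in range(n):
                    r = vals[i] if vals is not None else 5
                    reinforced = int(phase == "acquisition" and stim == "CS_plus" and i in reinf_slots)
                    rows.append((pid, phase, stim, i + 1, r, reinforced))
    return pd.DataFrame(
        rows, columns=["participant_id", "phase", "stimulus", "trial_index", "rating", "reinforced"]
    )


def make_roster(participants, families=None, zygosity="MZ", sex="F", age=23.0, flags=None):
    rows = []
    for i, pid in enumerate(participants):
        fam = (families or {}).get(pid, f"F{i:04d}")
        f = (flags or {}).get(pid, (0, 0, 0))
        rows.append((pid, fam, zygosity, sex if isinstance(sex, str) else sex[i],
                     age if np.isscalar(age) else age[i], *f))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "family_id", "zygosity", "sex", "age",
                 "excluded_headphones", "excluded_volume", "excluded_exit"],
    )


@pytest.fixture()
def trial_files(tmp_path):
    """Write a 3-participant complete-design dataset to CSV and return paths."""
    pids = ["P01", "P02", "P03"]
    trials = make_trials(pids)
    roster = make_roster(pids)
    tfile = tmp_path / "trials.csv"
    pfile = tmp_path / "participants.csv"
    trials.to_csv(tfile, index=False)
    roster.to_csv(pfile, index=False)
    return tfile, pfile
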