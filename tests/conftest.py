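import numpy as np
import pandas as pd
import pytest

from microflux import AbundanceMatrix, PresenceMatrix


def make_metadata(n_subjects, n_visits, prefix="S"):
    rows = [
        (f"{prefix}{s}V{v}", f"{prefix}{s}", v)
        for s in range(n_subjects)
        for v in range(1, n_visits + 1)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "visit_index"]).set_index(
        "sample_id"
    )


def presence_from_profiles(profiles: dict[str, list[list[int]]]) -> PresenceMatrix:
    """Build a PresenceMatrix from {species: [per-subject visit profiles]}."""
    n_subjects = len(next(iter(profiles.values())))
    n_visits = len(next(iter(profiles.values()))[0])
    md = make_metadata(n_subjects, n_visits)
    data = {
        sp: np.concatenate([np.asarray(p, bool) for p in paths])
        for sp, paths in profiles.items()
    }
    values = pd.DataFrame(data, index=md.index).T
    return PresenceMatrix(values, md)


@pytest.fixture
def small_metadata():
    return make_metadata(3, 4)


@pytest.fixture
def toy_abundance(small_metadata):
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.uniform(0, 100, (5, len(small_metadata))),
        index=pd.Index([f"sp{i}" for i in range(5)], name="species_id"),
        columns=small_metadata.index,
    )
    return AbundanceMatrix(values, small_metadata)
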