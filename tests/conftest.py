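from __future__ import annotations

import numpy as np
import pytest

from oplsage import SimulationConfig, default_manifest, generate_cohort
from oplsage.data_model import CohortTable, SubjectRecord
from oplsage.manifest import FeatureManifest


@pytest.fixture(scope="session")
def manifest():
    return default_manifest()


@pytest.fixture(scope="session")
def small_manifest():
    """A 5-feature manifest for fast unit tests."""
    return FeatureManifest(
        names=("thA", "thB", "thC", "volA", "volB"),
        kinds=("thickness", "thickness", "thickness", "volume", "volume"),
    )


def make_small_cohort(small_manifest, n=12, seed=0) -> CohortTable:
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        diag = ("CTL", "MCI", "AD")[i % 3]
        prog = (
            {m: ("progressed" if i % 2 else "stable") for m in (12, 18, 24, 36)}
            if diag == "MCI"
            else {}
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                diagnosis=diag,
                age=float(60 + rng.integers(0, 30)) + 0.25,
                sex="M" if i % 2 else "F",
                education=float(rng.integers(8, 20)),
                mmse=int(rng.integers(20, 31)),
                cdr=0.0 if diag == "CTL" else 0.5,
                apoe4="positive" if i % 3 == 0 else "negative",
                cohort="ADNI" if i % 2 else "ANM",
                features=rng.normal(size=len(small_manifest)),
                progression=prog,
            )
        )
    return CohortTable.from_subjects(subjects, small_manifest)


@pytest.fixture()
def small_cohort(small_manifest):
    return make_small_cohort(small_manifest)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort shared by read-only tests."""
    return generate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def tiny_sim_config(manifest):
    """A scaled-down simulation for fast end-to-end runs."""
    return SimulationConfig(n_ctl=60, n_mci_s=40, n_mci_p=20, n_ad=60, seed=3)
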