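from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from m6amir import thermo
from m6amir.datamodel import MiRNARecord
from m6amir.synthetic_data import SynthConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BASES = "ACGU"


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


@pytest.fixture(scope="session")
def params() -> thermo.EnergyParams:
    return thermo.default_params()


@pytest.fixture(scope="session")
def let7() -> MiRNARecord:
    return MiRNARecord("let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(
        SynthConfig(n_transcripts=120, rng_seed=7, n_chimeras=40)
    )
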