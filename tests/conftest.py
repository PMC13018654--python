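"""Shared fixtures: small montages, code tables and synthetic datasets.

Session-scoped fixtures cache the expensive synthetic datasets so the whole
suite generates each study condition once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from ssvepkit import montage as mon
from ssvepkit import pipeline
from ssvepkit.synthetic_data import SimConfig, synth_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

FS_SIM = 250.0  # generation rate used by the test suite (decoding rate)
SNR_DEFAULT = 12.0  # dB, the package's default study condition


@pytest.fixture(scope="session")
def montage9() -> mon.Montage:
    return mon.load_configuration("9/64")


@pytest.fixture(scope="session")
def montage66() -> mon.Montage:
    return mon.load_configuration("66/256")


@pytest.fixture(scope="session")
def codes40():
    """40-flicker table with the center fixation (frequency-phase coding only)."""
    return pipeline.build_codes(1, 5)


@pytest.fixture(scope="session")
def codes200():
    return pipeline.build_codes(5, 1)


@pytest.fixture(scope="session")
def noiseless_epochs40(montage9, codes40):
    """Three noiseless blocks of the 40-target task on the 9/64 montage."""
    cfg = SimConfig(
        montage=montage9, code_table=codes40, fs=FS_SIM, seed=7, target_snr_db=None
    )
    return synth_dataset(3, codes40, 0.8, cfg)


@pytest.fixture(scope="session")
def noisy_epochs40(montage9, codes40):
    """Four noisy blocks of the 40-target task at the default SNR."""
    cfg = SimConfig(
        montage=montage9,
        code_table=codes40,
        fs=FS_SIM,
        seed=11,
        target_snr_db=SNR_DEFAULT,
    )
    return synth_dataset(4, codes40, 0.68, cfg)
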