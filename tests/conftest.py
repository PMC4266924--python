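"""Shared fixtures and hypothesis configuration."""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nmrbind.io import Peak, PeakList, SequenceRecord
from nmrbind.peptide import bundled_xa2_sequence
from nmrbind.synthetic import default_mbp_scenario, simulate_titration

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def xa2() -> SequenceRecord:
    return bundled_xa2_sequence()


@pytest.fixture(scope="session")
def noiseless_series():
    """Noiseless default titration scenario (K_D 5 uM)."""
    return simulate_titration(default_mbp_scenario())


@pytest.fixture()
def simple_peaklist() -> PeakList:
    return PeakList(peaks=(
        Peak(delta_H=8.05, delta_N=118.2, residue_label="Y65", height=1.2e5),
        Peak(delta_H=8.31, delta_N=112.4, residue_label="T95"),
        Peak(delta_H=7.92, delta_N=121.7, residue_label="S38"),
        Peak(delta_H=8.30, delta_N=120.0),
    ), label="demo")


@pytest.fixture(autouse=True)
def _quiet_package_warnings():
    """Keep expected data-quality warnings out of the test log."""
    from nmrbind._util import NmrbindWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NmrbindWarning)
        yield


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
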