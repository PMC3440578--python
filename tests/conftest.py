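"""Shared fixtures: compact synthetic datasets sized for fast, exact checks."""

import numpy as np
import pytest

import biophyskit as bk
from biophyskit import reference as ref


@pytest.fixture(scope="session")
def small_irf():
    """1024-channel, 20-ps grid Gaussian IRF (fast test geometry)."""
    return bk.make_irf(peak_time=1.0, fwhm=0.3, n_channels=1024, channel_width=0.02)


@pytest.fixture(scope="session")
def study_irf():
    """The 4096-channel, 10-ps grid used for the full-scale recoveries."""
    return bk.make_irf(peak_time=2.0, fwhm=0.5, n_channels=4096, channel_width=0.01)


@pytest.fixture(scope="session")
def nterm_lifetimes():
    return ref.TRP_LIFETIMES["nterm_domain"]


@pytest.fixture(scope="session")
def nterm_anisotropy():
    return ref.TRP_ANISOTROPY["nterm_domain"]


@pytest.fixture(scope="session")
def single_tau():
    return bk.DecayComponents([1.0], [3.18])
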