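"""Shared fixtures: wavelet tables and the scaled-down benchmark suites."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from localves.basis import build_wavelet_basis, cascade_tabulate, symlet_filters
from localves.experiments import run_suite, suite_from_preset

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sym8_table():
    h, _ = symlet_filters(8)
    return cascade_tabulate(h)


@pytest.fixture(scope="session")
def sym10_table():
    h, _ = symlet_filters(10)
    return cascade_tabulate(h)


@pytest.fixture(scope="session")
def sym8_basis():
    """Sym8 basis with 22 functions on [-3, 3] (the benchmark setup)."""
    return build_wavelet_basis((-3.0, 3.0), 22, N=8)


@pytest.fixture(scope="session")
def quick_benchmark():
    """Scaled-down double-well benchmark: 5 runs x 5e5 steps per basis.

    Shared across the convergence and estimator-consistency checks so the
    expensive sampling happens once per session.
    """
    wav = run_suite(suite_from_preset("double_well_wavelet_quick"))
    leg = run_suite(suite_from_preset("double_well_legendre_quick"))
    assert not wav.failures and not leg.failures
    return {"wavelet": wav, "legendre": leg}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
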