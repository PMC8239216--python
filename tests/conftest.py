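"""Shared fixtures.

The expensive simulation artifacts (phantom, assembled dictionary, the
SNR-50 noise sweep and the trend sweeps) are session-scoped so that the
module tests and the acceptance tests reuse one computation.
"""

import numpy as np
import pytest

from axsize.experiments import (
    SweepConfig,
    run_dictionary_sweep,
    run_dispersion_sweep,
    run_snr_sweep,
)
from axsize.model import BundleDiameterModel
from axsize.phantom import build_phantom, default_bundles
from axsize.scheme import connectom_protocol

#: problem sizes for the desk-scale validation runs (single slice, 30
#: streamlines per bundle, 20 noise realizations)
PHANTOM_KW = dict(grid=(40, 40, 1), n_streamlines=30, seed=1)


@pytest.fixture(scope="session")
def protocol():
    return connectom_protocol()


@pytest.fixture(scope="session")
def phantom1():
    """Single-slice crossing phantom, no dispersion, noise-free."""
    return build_phantom(default_bundles(), **PHANTOM_KW)


@pytest.fixture(scope="session")
def bundle_model(phantom1):
    model = BundleDiameterModel.from_phantom(phantom1)
    model.operator  # assemble once
    return model


@pytest.fixture(scope="session")
def noise_free_results(bundle_model):
    return bundle_model.fit()


@pytest.fixture(scope="session")
def snr50_sweep():
    """20 Rician realizations at SNR 50, both methods, paired design."""
    return run_snr_sweep(SweepConfig(snr_grid=(50.0,), n_realizations=20, seed=1))


@pytest.fixture(scope="session")
def dict_sweep():
    """Diameter-grid density sweep at SNR 50 (2 paired realizations)."""
    return run_dictionary_sweep(
        SweepConfig(dictionary_sizes=(6, 9, 12, 15), n_realizations=2, seed=3)
    )


@pytest.fixture(scope="session")
def dispersion_sweep():
    """Watson dispersion sweep with surrogate tracking (2 realizations)."""
    return run_dispersion_sweep(
        SweepConfig(kappa_grid=(8.0, 16.0, np.inf), n_realizations=2, seed=5)
    )


def sweep_mean(df, method, target, value=None):
    sel = (df.method == method) & (df.target == target)
    if value is not None:
        sel &= df.value == value
    return float(df.loc[sel, "estimate"].mean())
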