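import numpy as np
import pytest

from trxss import ensemble_fit, synthetic_data
from trxss.scattering_calc import QGridSpec


@pytest.fixture(scope="session")
def toy_dimer():
    """Default 385-residue-per-chain two-chain toy dimer."""
    return synthetic_data.make_toy_dimer(seed=0)


@pytest.fixture(scope="session")
def truth_bundle():
    """(truth, dark, light_int, light_fin) on the default 0-1 1/A grid."""
    return synthetic_data.make_truth(seed=0)


@pytest.fixture(scope="session")
def wide_truth_bundle():
    """Truth on a grid extending through the solvent-heating band."""
    grid = QGridSpec(n_points=151, q_min=0.0, q_max=2.3)
    return synthetic_data.make_truth(seed=0, grid=grid)


@pytest.fixture(scope="session")
def search_ensembles(toy_dimer):
    """200 x 200 conformer pools with precomputed Debye member curves.

    Shared between the planted-pair search and its noisy recovery
    property so the 400 Debye sums are evaluated once per session.
    """
    dark, light = synthetic_data.make_ensembles(
        toy_dimer, n_dark=200, n_light=200, seed=42
    )
    dark_curves = ensemble_fit.compute_member_curves(dark)
    light_curves = ensemble_fit.compute_member_curves(light)
    return dark, light, dark_curves, light_curves


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
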