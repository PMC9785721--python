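import numpy as np
import pytest

from ramanmix.mcr import MCRConfig
from ramanmix.synthetic import (
    AcquisitionModel,
    ClassProfile,
    FluorescenceModel,
    RippleModel,
    build_component_library,
    cohort_profiles,
    default_component_specs,
    default_grid,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library(grid):
    names, s = build_component_library(grid)
    return names, s


@pytest.fixture(scope="session")
def quiet_acquisition():
    """No artifacts, no noise."""
    return AcquisitionModel(
        fluorescence=FluorescenceModel(enabled=False),
        ripple=RippleModel(enabled=False),
        target_snr=None,
    )


def make_pure3_profiles(n_pure=(15, 10, 5), n_mixed=(10, 10)):
    """Three-component profiles with exactly-pure classes plus mixtures.

    Zero mean + zero cv pins the minor components at exactly zero, so the
    non-negative factorization is identifiable.
    """
    zeros = {"melanin": 0.0, "proteins": 0.0, "water": 0.0}

    def prof(label, n, **means):
        m = dict(zeros, **means)
        cv = {k: (0.3 if v > 0 else 0.0) for k, v in m.items()}
        return ClassProfile(label, m, cv, n)

    return (
        prof("MM", n_pure[2], melanin=1.0),
        prof("BCC", n_pure[1], proteins=1.0),
        prof("NS", n_pure[0], water=1.0),
        prof("K", n_mixed[0], melanin=0.5, proteins=0.5, water=0.5),
        prof("PN", n_mixed[1], melanin=0.8, proteins=0.3, water=0.6),
    )


@pytest.fixture(scope="session")
def pure3_dataset(quiet_acquisition):
    """50 noiseless samples mixed from 3 components (identifiable)."""
    specs = default_component_specs()[:3]
    return simulate_dataset(
        profiles=make_pure3_profiles(),
        specs=specs,
        acquisition=quiet_acquisition,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(quiet_acquisition):
    """Default 4-component preset scaled down, noiseless."""
    counts = {"NS": 30, "K": 12, "BCC": 12, "MM": 8, "PN": 10}
    return simulate_dataset(
        profiles=cohort_profiles(counts=counts),
        acquisition=quiet_acquisition,
        seed=5,
    )


def matched_correlations(s_true, s_est, c_true=None, c_est=None):
    """Hungarian matching on spectral correlation; returns matched r values.

    If concentrations are given, also returns the concentration correlations
    under the same permutation.
    """
    from scipy.optimize import linear_sum_assignment

    a = s_true.shape[0]
    corr = np.corrcoef(np.vstack([s_true, s_est]))[:a, a:]
    rows, cols = linear_sum_assignment(-corr)
    spec_r = corr[rows, cols]
    if c_true is None:
        return spec_r
    cc = np.array(
        [np.corrcoef(c_true[:, i], c_est[:, j])[0, 1] for i, j in zip(rows, cols)]
    )
    return spec_r, cc


@pytest.fixture(scope="session")
def default_mcr_config():
    return MCRConfig(n_components=4)
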