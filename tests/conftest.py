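import dataclasses

import numpy as np
import pytest

from dietmm.model_inputs import bundle_to_arrays, BundleArrays, N_AGES
from dietmm.sampling import EffectModel, ParameterDraw
from dietmm.state_space import CONDITIONS, enumerate_states
from dietmm.synthetic_cprd import default_config, generate_bundle

_HAS_COND = np.array(
    [[c in s.physical for c in CONDITIONS] for s in enumerate_states()[:32]]
)


@pytest.fixture(scope="session")
def small_config():
    """Calibrated defaults with a small cohort for fast tests."""
    return dataclasses.replace(default_config(seed=7), n_men=3000, n_women=3000)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_arrays(small_bundle):
    return bundle_to_arrays(small_bundle)


@pytest.fixture(scope="session")
def effect():
    return EffectModel.default()


def make_draw(p_death=0.1, p_inc=0.0, prev=0.0, cost=0.0, utility=1.0, rr=1.0):
    """Constant-parameter draw for closed-form checks."""
    inc = np.full((32, 4, 7, 2), float(p_inc))
    inc[np.broadcast_to(_HAS_COND[:, :, None, None], inc.shape)] = np.nan
    return ParameterDraw(
        incidence_p=inc,
        mortality_p=np.full((32, 7, 2), float(p_death)),
        depression_prev=np.full((16, 7, 2), float(prev)),
        cost=np.full((32, 7, 2), float(cost)),
        utility=np.full((32, N_AGES), float(utility)),
        rr=np.full((4, 7), float(rr)),
    )


def make_arrays(entry_age=30, n=1.0, sex=0):
    """Minimal BundleArrays carrying only a cohort (for run_arm toy models)."""
    cohort = np.zeros((N_AGES, 2))
    cohort[entry_age - 30, sex] = n
    z32 = np.zeros((32, 7, 2))
    return BundleArrays(
        inc_k=np.zeros((32, 4, 7, 2)), inc_n=np.ones((32, 4, 7, 2)),
        mort_k=z32.copy(), mort_n=np.ones((32, 7, 2)),
        dep_k=np.zeros((16, 7, 2)), dep_n=np.ones((16, 7, 2)),
        cost_mean=z32.copy(), cost_sd=z32.copy(),
        util_mean=np.ones((32, N_AGES)), util_se=np.zeros((32, N_AGES)),
        cohort=cohort,
    )
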