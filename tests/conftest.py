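import numpy as np
import pytest

from copropk.population import (
    PopulationModel,
    RandomEffectsSpec,
    ResidualErrorSpec,
    reference_models,
)
from copropk.trial import default_design, simulate_trial


@pytest.fixture(scope="session")
def models():
    """Reference population models (rif, cpi, rsv) from the packaged table."""
    return reference_models()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def trial_df(models, design):
    """One seeded complete synthetic trial with residual noise."""
    rif, cpi, rsv = models
    return simulate_trial(design, rif, cpi, rsv, seed=1)


@pytest.fixture(scope="session")
def zero_var_models(models):
    """Models with all IIV/IOV variances removed (residual spec kept)."""
    out = []
    for pop in models:
        out.append(PopulationModel(
            fixed=pop.fixed,
            re=RandomEffectsSpec(omega2={k: 0.0 for k in pop.re.omega2},
                                 pi2={k: 0.0 for k in pop.re.pi2}),
            err=ResidualErrorSpec(dict(pop.err.streams)),
        ))
    return tuple(out)


@pytest.fixture(scope="session")
def rif_grid_profile(models):
    """Typical-subject RIF concentration on a fine grid, with the grid."""
    from copropk import gridsim

    rif = models[0]
    t = np.arange(0.0, 24.0001, 0.02)
    p = {k: np.array([getattr(rif.fixed, k)]) for k in ("ka", "CL", "V", "MTT", "n")}
    p["dose_umol"] = np.array([rif.fixed.dose_umol])
    return t, gridsim.rif_profile(p, t)[0]
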