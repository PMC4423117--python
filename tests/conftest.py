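"""Shared fixtures: reference parameters and reusable converged runs.

The expensive wild-type simulations are session-scoped so that the
refinement, threshold and persistence tests can share them instead of
re-integrating the same trajectory.
"""

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dvpattern as dv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> dv.ModelParameters:
    return dv.ModelParameters()


def _wt(D0=0.3, nx=256, dt=2.0, **kw):
    sc = dv.ScenarioConfig(f"wt:D0={D0}", profile=dv.ProfileSpec(D0=D0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return dv.run_scenario(sc, nx=nx, dt=dt, **kw)


@pytest.fixture(scope="session")
def wt_run(params):
    """Converged wild-type 1D run (D0 = 0.3, nx = 256, dt = 2)."""
    return _wt()


@pytest.fixture(scope="session")
def wt_run_dt_half(params):
    """Same trajectory integrated at half the step size."""
    return _wt(dt=1.0)


@pytest.fixture(scope="session")
def wt_run_fine(params):
    """Same problem on a twice-finer grid."""
    return _wt(nx=512)


@pytest.fixture(scope="session")
def wt_run_high_dorsal(params):
    """Wild type with a saturating initial Dorsal amplitude (D0 = 1)."""
    return _wt(D0=1.0)


@pytest.fixture(scope="session")
def subthreshold_run(params):
    """Initial Dorsal amplitude below the patterning threshold."""
    return _wt(D0=0.15)


@pytest.fixture(scope="session")
def knockdown_panel(params):
    """All six knockdown scenarios, run once."""
    out = {}
    for name in ("dpp_kd", "sog_kd", "tsg_kd", "tld_kd", "toll_kd", "toll_dpp_kd"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = dv.run_scenario(name, nx=128)
    return out


def draw_table2_parameters(rng: np.random.Generator) -> tuple[dv.ModelParameters, float]:
    """One random parameter set within the single-stripe ranges.

    Returns the parameters and a Dorsal level drawn so the expression
    rate lies inside its printed range."""
    def loguni(lo, hi):
        lo = max(lo, hi * 1e-3)  # avoid zero endpoints for log draws
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    t2 = dv.TABLE2_RANGES
    p = dv.ModelParameters(
        b0=loguni(*t2["b0"]), eta_b=loguni(*t2["eta_b"]),
        alpha_s=loguni(*t2["alpha_s"]), alpha_b=loguni(1e-5, t2["alpha_b"][1]),
        k_plus=loguni(*t2["k_plus"]), k_minus=loguni(*t2["k_minus"]),
        D_s=loguni(*t2["D_s"]), D_b=loguni(*t2["D_b"]), D_c=loguni(*t2["D_c"]),
    )
    d = dv.dorsal_for_eta_bar(loguni(*t2["eta_bar"]), p)
    return p, d
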