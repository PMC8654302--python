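import numpy as np
import pytest

from mthet.oocyte_sim import SimParams
from mthet.synthetic_data import SynthConfig

# scaled-down study conditions shared by the inference-level tests:
# antral endpoint 5000 copies instead of 1.41e5 so a cohort simulates in
# milliseconds while keeping hundreds of replication iterations per cell
SCALED_N_FINAL = 5_000
SCALED_T_MAX = 1_500
SCALED_MILESTONES = {"primary": int(SCALED_N_FINAL * 0.021),
                     "secondary": int(SCALED_N_FINAL * 0.14)}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def scaled_params(H=4, lam_m=0.5, lam_w=0.5, **kw) -> SimParams:
    kw.setdefault("R0", 100)
    kw.setdefault("N_final", SCALED_N_FINAL)
    kw.setdefault("t_max", SCALED_T_MAX)
    return SimParams(lambda_m=lam_m, lambda_w=lam_w, H=H, **kw)


def scaled_config(params, **kw) -> SynthConfig:
    kw.setdefault("n_mothers", 6)
    kw.setdefault("cells_per_stage", 8)
    kw.setdefault("antral_mean", float(SCALED_N_FINAL))
    kw.setdefault("antral_sd", SCALED_N_FINAL * 0.3)
    return SynthConfig(sim_params=params, **kw)
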