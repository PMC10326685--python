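import numpy as np
import pytest

import imatinib_pbpk as ip


@pytest.fixture(scope="session")
def cfg():
    return ip.load_default_config()


@pytest.fixture(scope="session")
def drug(cfg):
    return cfg.drug


@pytest.fixture(scope="session")
def system(cfg):
    return cfg.system


@pytest.fixture(scope="session")
def regimen_ss():
    """Standard steady-state regimen: 400 mg once daily for 14 days."""
    return ip.DoseRegimen(dose=400.0, interval=24.0, n_doses=14)


REFERENCE_OVERRIDES = {
    "weight": 81.0, "height": 176.0, "serum_creatinine": 80.0,
    "CYP3A4_hepatic": 93.0, "CYP2C8_hepatic": 22.4, "CYP3A4_gut": 66.0,
    "P-gp": 0.201, "BCRP": 0.044, "AAG": 0.91,
}


@pytest.fixture(scope="session")
def ref_ind(cfg):
    """A reference adult with all sampled physiology pinned at its mean."""
    ind = ip.sample_individual(cfg.system, {"age": 50, "sex": "M"}, seed=1,
                               drug=cfg.drug, overrides=REFERENCE_OVERRIDES)
    ind.mppgl = cfg.system.mppgl.mean
    return ind


@pytest.fixture(scope="session")
def pop_opts():
    return ip.SolverOptions.population()


@pytest.fixture(scope="session")
def ref_ss_result(cfg, ref_ind, regimen_ss, pop_opts):
    """Reference 14-day steady-state simulation, shared across tests."""
    return ip.simulate(ref_ind, cfg.drug, regimen_ss, options=pop_opts,
                       kdeg=cfg.system.kdeg)
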