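"""Shared fixtures: one synthetic study (flow record, samples, fitted model).

Session scope keeps the expensive pieces (17-year record, penalized fit) to a
single computation reused across test modules.
"""

import numpy as np
import pytest

import estuarylink as el


def season_effect(yday):
    return 0.2 * np.sin(2 * np.pi * np.asarray(yday, dtype=float) / 366)


def flow_effect(log1pq):
    return 0.3 * np.tanh(np.asarray(log1pq, dtype=float) - 5.0)


def ma_effect(ma):
    return 0.1 * np.tanh(np.asarray(ma, dtype=float) - 5.0)


@pytest.fixture(scope="session")
def flow17():
    return el.generate_discharge(el.FlowGenConfig(seed=3, n_years=17))


@pytest.fixture(scope="session")
def cov17(flow17):
    return el.build_covariates(flow17, "ltfa")


@pytest.fixture(scope="session")
def pred_cov17(cov17):
    return cov17[~cov17["warmup"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def conc_config():
    return el.ConcGenConfig(
        seed=5,
        intercept=float(np.log(0.2)),
        season_fn=season_effect,
        flow_fn=flow_effect,
        ma_fn=ma_effect,
        noise_sd=0.04,
    )


@pytest.fixture(scope="session")
def samples17(flow17, conc_config):
    return el.generate_concentration_samples(flow17, conc_config)


@pytest.fixture(scope="session")
def rating_model(samples17, cov17):
    return el.fit_concentration_model(
        el.substitute_censored(samples17), cov17, optimizer_maxfev=80
    )
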