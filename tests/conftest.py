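import numpy as np
import pandas as pd
import pytest

from duocomb import (DesignConfig, MTDCurve, SamplerSettings, ToxParams,
                     build_scenario)
from duocomb.efficacy import EfficacyMAC, EfficacyResults
from duocomb.sampling import SamplerDiagnostics
from duocomb.toxicity import ToxicityModel, ToxicityResults


@pytest.fixture(scope="session")
def tox_params_1():
    """First default toxicity truth: symmetric corners, curve through (1/3, 1/2)."""
    return ToxParams(rho00=0.01, rho01=0.2, rho10=0.2, alpha3=7.2775)


@pytest.fixture(scope="session")
def curve_1(tox_params_1):
    return MTDCurve(tox_params=tox_params_1, theta_T=0.33)


@pytest.fixture(scope="session")
def scenario_h1_ca():
    return build_scenario(1, 1, "H1", "CA")


@pytest.fixture(scope="session")
def sim_config():
    return DesignConfig(omega=0.0, sampler=SamplerSettings.for_simulation())


def point_mass_tox_results(params: ToxParams, n: int = 100) -> ToxicityResults:
    """A degenerate toxicity posterior: every draw equals ``params``."""
    draws = pd.DataFrame({
        "rho00": np.full(n, params.rho00), "rho01": np.full(n, params.rho01),
        "rho10": np.full(n, params.rho10), "alpha3": np.full(n, params.alpha3),
    })
    return ToxicityResults(model=ToxicityModel(), draws=draws,
                           diagnostics=SamplerDiagnostics(1.0, n))


def synthetic_eff_results(stage2_rows: np.ndarray) -> EfficacyResults:
    """EfficacyResults from explicit stage-2 draws (beta0_2..beta3_2 columns)."""
    n = stage2_rows.shape[0]
    draws = pd.DataFrame({
        "beta0_1": np.zeros(n), "beta1_1": np.zeros(n), "beta2_1": np.zeros(n),
        "beta3_1": np.zeros(n),
        "beta0_2": stage2_rows[:, 0], "beta1_2": stage2_rows[:, 1],
        "beta2_2": stage2_rows[:, 2], "beta3_2": stage2_rows[:, 3],
        "mu1": np.zeros(n), "mu2": np.zeros(n),
        "tau1": np.full(n, 0.5), "tau2": np.full(n, 0.5),
        "xi": np.full(n, 0.25), "zeta": np.full(n, 0.25),
        "exch_prob": np.zeros(n),
    })
    return EfficacyResults(model=EfficacyMAC(), draws=draws,
                           diagnostics=SamplerDiagnostics(1.0, n))


def make_records(xs, ys, zs, es=None, stage=1) -> pd.DataFrame:
    n = len(xs)
    return pd.DataFrame({
        "patient_id": np.arange(1, n + 1), "stage": stage,
        "x_std": xs, "y_std": ys, "x_raw": np.nan, "y_raw": np.nan,
        "dlt": zs, "eff": es if es is not None else np.nan, "cohort": 0,
    })
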