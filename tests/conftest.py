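"""Shared fixtures and the independent direct-summation metric oracle.

The oracle deliberately avoids the package's vectorized code paths: pure
Python loops and ``math`` only, so it can arbitrate the NumPy
implementations.
"""

from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import settings

from mpyeval.simulate import GeneratorConfig, generate_herd_set

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


def oracle_metrics(obs, pred):
    """Direct-summation agreement metrics (population moments)."""
    n = len(obs)
    mo = sum(obs) / n
    mp = sum(pred) / n
    var_o = sum((o - mo) ** 2 for o in obs) / n
    var_p = sum((p - mp) ** 2 for p in pred) / n
    cov = sum((o - mo) * (p - mp) for o, p in zip(obs, pred)) / n
    mse = sum((o - p) ** 2 for o, p in zip(obs, pred)) / n
    out = {"mse": mse, "rmse": math.sqrt(mse), "nrmse": math.sqrt(mse) / mo,
           "mean_obs": mo, "mean_pred": mp}
    s_o, s_p = math.sqrt(var_o), math.sqrt(var_p)
    if s_o > 0 and s_p > 0:
        r = cov / (s_o * s_p)
        ccc = 2 * cov / (var_o + var_p + (mo - mp) ** 2)
        out.update(r=r, ccc=ccc, cb=ccc / r)
    else:
        r = 0.0
    out["ctb"] = (mp - mo) ** 2
    out["rb"] = (s_p - r * s_o) ** 2
    out["db"] = (1 - r**2) * var_o
    return out


@pytest.fixture(scope="session")
def toy5():
    """Mean-shift-only toy pair: pred = obs + 1."""
    return [1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 3.0, 4.0, 5.0, 6.0]


@pytest.fixture(scope="session")
def toy3():
    """Slope-bias toy pair: pred = 2 * obs, r = 1."""
    return [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]


@pytest.fixture(scope="session")
def small_config():
    """A fast 6-herd / 120-cow generator configuration."""
    return GeneratorConfig(n_herds=6, n_cows=120)


@pytest.fixture(scope="session")
def small_herd_set(small_config):
    return generate_herd_set(small_config, seed=7)


@pytest.fixture()
def cow_csv(tmp_path):
    """A tiny well-formed cow table on disk."""
    path = tmp_path / "cows.csv"
    pd.DataFrame({
        "cow_id": ["C1", "C2", "C3"],
        "herd_id": ["H1", "H1", "H2"],
        "parity": [1, 2, 3],
        "bw_kg": [612.0, 672.0, 700.0],
        "dim_d": [100, 202, 300],
        "mpy_obs_g_d": [800.0, 894.0, 1000.0],
        "rha_kg_305d": [280.0, None, 310.0],
    }).to_csv(path, index=False)
    return path
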