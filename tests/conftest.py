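import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dlptp.data import TwoDDataset, add_log10_conc, assign_runs
from dlptp.models import ProfileData

TEMPS = np.array([42.0, 44.1, 46.2, 48.1, 50.4, 51.9, 54.0, 56.1, 58.2, 60.1, 62.4, 63.9])
CONCS_M = np.array([0.0, 4e-8, 2.9e-7, 2e-6, 1e-5])   # mol/L, vehicle first


def log10_concs(conc_offset: float = 2.0) -> np.ndarray:
    nz = np.log10(CONCS_M[CONCS_M > 0])
    return np.concatenate([[nz.min() - conc_offset], nz])


def make_profile(pid: str, y: np.ndarray, temps: np.ndarray = TEMPS) -> ProfileData:
    """ProfileData on the full temps x concs grid from a (m, n) value matrix."""
    m, n = temps.size, CONCS_M.size
    assert y.shape == (m, n)
    tcode = np.repeat(np.arange(m), n)
    return ProfileData(
        protein_id=pid,
        y=y.ravel(),
        c=np.tile(log10_concs(), m),
        temp=np.repeat(temps, n),
        temp_code=tcode,
        temps=temps,
        run_code=tcode // 2,
        runs=np.arange((m + 1) // 2),
    )


def sigmoid_profile(rng, delta=1.5, kappa=8.0, pec50=6.0, a=0.0, sigma=0.05,
                    temps: np.ndarray = TEMPS, alpha_mid=52.0, alpha_width=2.0):
    """Grid of values from the dose-response model plus Gaussian noise."""
    c = log10_concs()
    beta = 10.0 + np.log2(expit(0.5 * (53.0 - temps)) * 0.9 + 0.1)
    alpha = expit((temps - alpha_mid) / alpha_width)
    t_mid = temps.mean()
    zeta = -pec50 - a * t_mid + a * temps
    resp = alpha[:, None] * delta * expit(kappa * (c[None, :] - zeta[:, None]))
    y = beta[:, None] + resp
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, y.shape)
    return y


def flat_profile(rng, sigma=0.08, temps: np.ndarray = TEMPS):
    beta = 10.0 + np.log2(expit(0.5 * (53.0 - temps)) * 0.9 + 0.1)
    y = np.tile(beta[:, None], (1, CONCS_M.size))
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, y.shape)
    return y


def make_dataset(values: dict[str, np.ndarray], temps: np.ndarray = TEMPS) -> TwoDDataset:
    """TwoDDataset from {protein_id: (m, n) value grid} (NaN = missing)."""
    rows = []
    for pid, grid in values.items():
        for j, t in enumerate(temps):
            for k, conc in enumerate(CONCS_M):
                rows.append((pid, t, conc, grid[j, k]))
    df = pd.DataFrame(rows, columns=["protein_id", "temperature", "conc", "log2_value"])
    df = add_log10_conc(df)
    df = assign_runs(df)
    return TwoDDataset(df)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
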