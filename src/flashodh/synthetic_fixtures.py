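"""Seeded generators for every input the pipelines consume.

No public dataset ships with the experiments this package recreates, so all
pipeline tests run on synthetic stand-ins that reproduce the *structure* of
the originals:

* saturation-shaped damage-vs-pO2 tables with additive Gaussian noise, for
  response-curve fitting;
* single/double-pulse survival records on a 0.5-45 Gy dose ladder, built
  from a linear-quadratic survival model on the sparing-effective dose with
  double-pulse measurements derived by algebraically inverting the survival
  correction, so the pipeline provably restores the single-pulse curve;
* a dose-rate sweep whose behavioural responses are a monotone (plus noise)
  function of the physics-path inverse sparing;
* piecewise-constant 3D dose/oxygen phantoms.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .damage_response import DEFAULT_RESPONSE, OxygenResponseParams, oxygen_response
from .experiments import RecognitionConfig, TownConfig, town_sparing
from .sparing import linear_sparing_factor
from .voxel_engine import VoxelGrid

__all__ = [
    "gen_response_table",
    "gen_town_survival",
    "gen_recognition_sweep",
    "gen_phantom",
    "MONTAY_GRUEL_RATES",
]

#: The mean dose rates (Gy/s) of the pulsed arms in the mouse cognition sweep.
MONTAY_GRUEL_RATES = (0.1, 1.0, 3.0, 10.0, 20.0, 30.0, 60.0, 100.0, 500.0)

#: Fixture linear-quadratic survival parameters (generic mammalian-cell
#: scale); a fixture convention for round-trip testing, not a data claim.
DEFAULT_LQ_ALPHA = 0.3
DEFAULT_LQ_BETA = 0.03


def gen_response_table(
    params: OxygenResponseParams = DEFAULT_RESPONSE,
    o2_grid: Sequence[float] = (0.0, 2.0, 5.0, 10.0, 20.0, 76.0, 152.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """(o2_torr, yield) table from the rational response plus Gaussian noise.

    ``noise_sd`` is relative: the additive noise sd is noise_sd * yield.
    """
    o2 = np.asarray(o2_grid, dtype=float)
    if o2.size == 0:
        raise ValueError("o2 grid is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = oxygen_response(o2, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * y)
    return pd.DataFrame({"o2_torr": o2, "yield": y})


def lq_survival(dose, alpha: float = DEFAULT_LQ_ALPHA, beta: float = DEFAULT_LQ_BETA):
    """Linear-quadratic survival exp(-alpha*D - beta*D^2)."""
    dose = np.asarray(dose, dtype=float)
    out = np.exp(-alpha * dose - beta * dose * dose)
    return float(out) if out.ndim == 0 else out


def gen_town_survival(
    doses: Optional[Sequence[float]] = None,
    alpha: float = DEFAULT_LQ_ALPHA,
    beta: float = DEFAULT_LQ_BETA,
    config: TownConfig = TownConfig(),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic single/double-pulse survival records.

    Single-pulse ground truth is LQ survival on the sparing-effective dose
    D * F1(D).  Double-pulse measured survival is derived by inverting the
    correction SF_corr = 1 - (1 - SF_meas) * F2, with F2 the double-pulse
    sparing factor, so that correcting it restores the single-pulse curve.
    The inversion requires 1 - SF_single(D) <= F2(D); records where the
    default survival model violates this (very high dose combined with
    strong sparing) are flagged ``infeasible`` and their sf_meas clamped
    to 0.  Optional multiplicative lognormal noise with sigma ``noise_sd``
    is applied to the measured fractions.
    """
    if doses is None:
        doses = np.geomspace(0.5, 45.0, 12)
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        f1 = town_sparing(d, 1, config)
        f2 = town_sparing(d, 2, config)
        sf_single = float(lq_survival(d * f1, alpha, beta))
        sf_double = 1.0 - (1.0 - sf_single) / f2
        infeasible = sf_double < 0.0
        sf_double = max(sf_double, 0.0)
        rows.append((d, sf_single, 1, sf_single, False))
        rows.append((d, sf_double, 2, sf_single, infeasible))
    df = pd.DataFrame(
        rows, columns=["dose_gy", "sf_meas", "n_pulses", "sf_true", "infeasible"]
    )
    if noise_sd > 0:
        noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=len(df))
        df["sf_meas"] = np.clip(df["sf_meas"] * noise, 0.0, 1.0)
    return df


def gen_recognition_sweep(
    dose_rates: Sequence[float] = MONTAY_GRUEL_RATES,
    baseline: float = 0.5,
    slope: float = 0.2,
    noise_sd: float = 0.02,
    seed: int = 0,
    config: RecognitionConfig = RecognitionConfig(),
    include_single_pulse: bool = True,
) -> pd.DataFrame:
    """Dose-rate arms with responses linked to the physics-path sparing.

    Responses are baseline + slope * (1/F) + Gaussian noise, where F is the
    per-pulse sparing factor computed exactly as the recreation pipeline
    computes it, so a noiseless sweep correlates perfectly (rho = 1).
    """
    rates = np.asarray(dose_rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("dose rates must be > 0")
    rng = np.random.default_rng(seed)
    labels = [f"{r:g} Gy/s" for r in rates]
    single = [False] * rates.size
    dpp = rates / config.prf
    if include_single_pulse:
        labels.append("1 pulse")
        single.append(True)
        dpp = np.append(dpp, config.total_dose)
        rates = np.append(rates, np.nan)
    factors = linear_sparing_factor(config.o2_0, config.rate, dpp, config.response)
    responses = baseline + slope / factors
    if noise_sd > 0:
        responses = responses + rng.normal(0.0, noise_sd, size=responses.size)
    return pd.DataFrame(
        {
            "label": labels,
            "mean_rate_gy_s": rates,
            "single_pulse": single,
            "response": responses,
        }
    )


def gen_phantom(
    shape: tuple[int, int, int] = (16, 16, 16),
    background_dose: float = 15.0,
    background_o2: float = 20.0,
    regions: Sequence[dict] = (),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
    dose_jitter_sd: float = 0.0,
) -> tuple[VoxelGrid, VoxelGrid]:
    """Dose and oxygen grids with spherical regions on a uniform background.

    Each region is a dict with keys ``center`` (voxel indices), ``radius``
    (voxels) and optional ``dose`` / ``o2`` overrides.  ``dose_jitter_sd``
    adds seeded Gaussian jitter to the dose grid (clipped at 0) to exercise
    heterogeneous inputs.
    """
    dose = np.full(shape, float(background_dose))
    o2 = np.full(shape, float(background_o2))
    ix, iy, iz = np.indices(shape)
    for region in regions:
        cx, cy, cz = region["center"]
        r = region["radius"]
        mask = (ix - cx) ** 2 + (iy - cy) ** 2 + (iz - cz) ** 2 <= r * r
        if "dose" in region:
            dose[mask] = region["dose"]
        if "o2" in region:
            o2[mask] = region["o2"]
    if dose_jitter_sd > 0:
        rng = np.random.default_rng(seed)
        dose = np.clip(dose + rng.normal(0.0, dose_jitter_sd, size=shape), 0.0, None)
    return VoxelGrid(dose, spacing), VoxelGrid(o2, spacing)
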