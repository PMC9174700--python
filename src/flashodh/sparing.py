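"""FLASH sparing factors derived from oxygen dose histograms.

The total complex-damage count under an ODH is

    M_D = sum_i dose_i * F(pO2 at bin midpoint i)

and M_D0 = D * F(pO2_0) is the damage had the oxygenation stayed at its
initial level throughout delivery.  The ratio F_spare = M_D / M_D0 is <= 1
whenever the trajectory never exceeds pO2_0, and quantifies the FLASH
sparing effect (smaller = more sparing).  Measured survival under a
delivery with sparing factor F is mapped back to a no-sparing equivalent by
rescaling the killed fraction:  SF_corr = 1 - (1 - SF_meas) * F.

For the linear depletion model the trajectory integral has a closed form,

    M_D = (1/R) * [C1*(x0 - x_end) - (C1*C3 - C2) * ln((x0+C3)/(x_end+C3))]
          + max(D - x0/R, 0) * C2/C3,      x_end = max(x0 - R*D, 0),

implemented here both as the fast path for voxelised evaluation and as an
internal oracle for the binned path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .damage_response import DEFAULT_RESPONSE, OxygenResponseParams, oxygen_response
from .depletion import LinearDepletionModel, linear_trajectory
from .odh_core import DEFAULT_BIN_WIDTH, OxygenDoseHistogram, odh_from_trajectory

__all__ = [
    "SparingResult",
    "total_damage",
    "sparing_factor",
    "linear_total_damage",
    "linear_sparing_factor",
    "correct_survival",
    "sparing_vs_dose",
    "sparing_vs_o2",
    "crossover_dose",
]


@dataclass(frozen=True)
class SparingResult:
    """Damage totals and the derived sparing factor for one delivery."""

    m_d: float          # lesions per cell per Gbp under the ODH
    m_d0: float         # same at constant initial pO2
    factor: float       # m_d / m_d0
    total_dose: float   # Gy
    o2_0: float         # Torr

    @property
    def relative_sparing(self) -> float:
        """1 - factor: the fraction of damage avoided."""
        return 1.0 - self.factor

    @property
    def inverse_factor(self) -> float:
        """1 / factor, the framing used against behavioural response data."""
        return 1.0 / self.factor


def total_damage(
    odh: OxygenDoseHistogram,
    response: OxygenResponseParams = DEFAULT_RESPONSE,
) -> float:
    """Total lesion count under the histogram (bin-midpoint evaluation)."""
    return float(np.sum(odh.doses * oxygen_response(odh.midpoints, response)))


def sparing_factor(
    odh: OxygenDoseHistogram,
    o2_0: float,
    response: OxygenResponseParams = DEFAULT_RESPONSE,
) -> SparingResult:
    """Sparing factor M_D / M_D0 of a delivery described by ``odh``."""
    d = odh.total_dose
    if d <= 0:
        raise ValueError("ODH carries zero dose")
    m_d = total_damage(odh, response)
    m_d0 = d * oxygen_response(o2_0, response)
    return SparingResult(m_d=m_d, m_d0=m_d0, factor=m_d / m_d0, total_dose=d, o2_0=o2_0)


def linear_total_damage(
    o2_0,
    rate,
    dose,
    response: OxygenResponseParams = DEFAULT_RESPONSE,
):
    """Closed-form trajectory integral of the response under linear depletion.

    Vectorised over ``o2_0`` and ``dose`` (numpy broadcasting); ``rate`` is
    Torr/Gy.  rate == 0 degenerates to dose * F(o2_0).
    """
    c1, c2, c3 = response.c1, response.c2, response.c3
    o2_0 = np.asarray(o2_0, dtype=float)
    dose = np.asarray(dose, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(o2_0 < 0) or np.any(dose < 0) or np.any(rate < 0):
        raise ValueError("o2_0, rate and dose must all be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        o2_end = np.maximum(o2_0 - rate * dose, 0.0)
        bracket = c1 * (o2_0 - o2_end) - (c1 * c3 - c2) * np.log(
            (o2_0 + c3) / (o2_end + c3)
        )
        oxic = np.where(rate > 0, bracket / np.where(rate > 0, rate, 1.0), 0.0)
        d_hyp = np.where(rate > 0, o2_0 / np.where(rate > 0, rate, 1.0), np.inf)
        hypoxic = np.maximum(dose - d_hyp, 0.0) * (c2 / c3)
        flat = dose * oxygen_response(np.maximum(o2_0, 0.0), response)
        out = np.where(rate > 0, oxic + hypoxic, flat)
    return float(out) if out.ndim == 0 else out


def linear_sparing_factor(
    o2_0,
    rate,
    dose,
    response: OxygenResponseParams = DEFAULT_RESPONSE,
):
    """Closed-form sparing factor under single-pulse linear depletion."""
    o2_0 = np.asarray(o2_0, dtype=float)
    dose = np.asarray(dose, dtype=float)
    m_d = linear_total_damage(o2_0, rate, dose, response)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            dose > 0,
            m_d / np.where(dose > 0, dose, 1.0) / oxygen_response(o2_0, response),
            1.0,
        )
    return float(out) if np.ndim(out) == 0 else out


def correct_survival(sf_meas, factor):
    """No-sparing-equivalent survival: SF_corr = 1 - (1 - SF_meas) * F."""
    sf_meas = np.asarray(sf_meas, dtype=float)
    factor = np.asarray(factor, dtype=float)
    if np.any((sf_meas < 0) | (sf_meas > 1)):
        raise ValueError("measured survival fraction must be in [0, 1]")
    if np.any((factor <= 0) | (factor > 1)):
        raise ValueError("sparing factor must be in (0, 1]")
    out = 1.0 - (1.0 - sf_meas) * factor
    return float(out) if out.ndim == 0 else out


def _binned_sparing(o2_0, rate, dose, response, bin_width):
    model = LinearDepletionModel(o2_0=o2_0, rate_r=rate)
    odh = odh_from_trajectory(linear_trajectory(model, dose), bin_width=bin_width)
    return sparing_factor(odh, o2_0, response).factor


def sparing_vs_dose(
    o2_0: float,
    model: LinearDepletionModel,
    doses,
    response: OxygenResponseParams = DEFAULT_RESPONSE,
    bin_width: Optional[float] = None,
) -> pd.DataFrame:
    """Sparing-factor sweep over a dose grid at fixed initial pO2.

    Uses the closed-form integral unless ``bin_width`` forces the binned
    histogram path.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("dose grid is empty")
    if bin_width is None:
        factors = linear_sparing_factor(o2_0, model.rate_r, doses, response)
    else:
        factors = np.array(
            [_binned_sparing(o2_0, model.rate_r, d, response, bin_width) for d in doses]
        )
    return pd.DataFrame({"dose_gy": doses, "o2_torr": o2_0, "sparing_factor": factors})


def sparing_vs_o2(
    dose: float,
    model: LinearDepletionModel,
    o2_grid,
    response: OxygenResponseParams = DEFAULT_RESPONSE,
    bin_width: Optional[float] = None,
) -> pd.DataFrame:
    """Sparing-factor sweep over initial pO2 at fixed dose."""
    o2_grid = np.asarray(o2_grid, dtype=float)
    if o2_grid.size == 0:
        raise ValueError("pO2 grid is empty")
    if bin_width is None:
        factors = linear_sparing_factor(o2_grid, model.rate_r, dose, response)
    else:
        factors = np.array(
            [_binned_sparing(o, model.rate_r, dose, response, bin_width) for o in o2_grid]
        )
    return pd.DataFrame({"dose_gy": dose, "o2_torr": o2_grid, "sparing_factor": factors})


def crossover_dose(
    o2_a: float,
    o2_b: float,
    model: LinearDepletionModel,
    bracket: tuple[float, float] = (0.1, 1e4),
    response: OxygenResponseParams = DEFAULT_RESPONSE,
    xtol: float = 1e-6,
) -> Optional[float]:
    """Dose at which the sparing curves of two initial pO2 levels cross.

    At low doses the lower-pO2 tissue is spared more; at high doses the
    asymptotes F(0)/F(o2_0) reverse the ordering, so a unique crossover
    exists.  Returns the root of sparing(o2_a, D) - sparing(o2_b, D) to
    ``xtol`` Gy, or None when the difference does not change sign over the
    bracket (no crossover).
    """

    def diff(d):
        return linear_sparing_factor(o2_a, model.rate_r, d, response) - \
            linear_sparing_factor(o2_b, model.rate_r, d, response)

    if o2_a == o2_b:
        return None
    lo, hi = bracket
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo * f_hi > 0:
        return None
    if f_lo == 0.0:
        return float(lo)
    return float(optimize.brentq(diff, lo, hi, xtol=xtol))
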