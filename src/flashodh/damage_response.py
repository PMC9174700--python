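"""Oxygen-fixation damage-response model.

Radiation-induced complex DNA lesions (double-strand-break class and worse)
are chemically "fixed" by molecular oxygen in competition with thiol-mediated
chemical repair.  Treating the fixation sites as a saturable ligand-receptor
system gives a Michaelis-Menten-shaped dependence of lesion yield on pO2.
Composed with a linear transform per particle energy this yields the
three-parameter rational response

    F(pO2) = (C1 * pO2 + C2) / (pO2 + C3)        [lesions / cell / Gbp / Gy]

which rises from the hypoxic floor C2/C3 towards the aerobic asymptote C1
with half-saturation scale C3 (Torr).  The shipped default parameter set is
the 2 MeV electron fit (C1 = 8.334, C2 = 15.99, C3 = 5.67); for photon and
electron beams in the clinical energy range the oxygen effect is very nearly
energy independent, so this single set is used directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from .errors import ConfigurationError, FitError

__all__ = [
    "SaturationParams",
    "DamageCoefficients",
    "OxygenResponseParams",
    "DEFAULT_RESPONSE",
    "saturation_response",
    "oxygen_response",
    "damage_yield",
    "fit_response_params",
    "spectrum_weighted_response",
]


@dataclass(frozen=True)
class SaturationParams:
    """Ligand-receptor saturation parameters of oxygen fixation.

    ``k_d`` is the effective dissociation constant (Torr-equivalent
    concentration; effective because fixation competes with thiol repair) and
    ``m_t`` the maximal number of fixation sites.  The derived coefficients
    q1 = k_d / m_t and q2 = 1 / m_t put the response in the rational form
    pO2 / (q1 + q2 * pO2).
    """

    k_d: float
    m_t: float

    def __post_init__(self):
        if self.k_d <= 0 or self.m_t <= 0:
            raise ConfigurationError(
                f"k_d and m_t must be positive, got k_d={self.k_d}, m_t={self.m_t}"
            )

    @property
    def q1(self) -> float:
        return self.k_d / self.m_t

    @property
    def q2(self) -> float:
        return 1.0 / self.m_t


@dataclass(frozen=True)
class OxygenResponseParams:
    """Parameters of the rational lesion-yield response F(pO2).

    c1 is the well-oxygenated asymptotic yield, c2/c3 the fully hypoxic
    floor, c3 the half-saturation pO2 scale in Torr.  The constraint
    c1*c3 >= c2 guarantees a non-decreasing response.
    """

    c1: float
    c2: float
    c3: float

    def __post_init__(self):
        if self.c3 <= 0:
            raise ConfigurationError(f"c3 must be > 0, got {self.c3}")
        if self.c2 < 0:
            raise ConfigurationError(f"c2 must be >= 0, got {self.c2}")
        if self.c1 * self.c3 < self.c2 * (1.0 - 1e-9):
            raise ConfigurationError(
                "c1*c3 >= c2 required for a non-decreasing response, got "
                f"c1*c3={self.c1 * self.c3} < c2={self.c2}"
            )

    @property
    def hypoxic_floor(self) -> float:
        """Lesion yield per Gy at pO2 = 0."""
        return self.c2 / self.c3

    def to_yaml(self) -> str:
        return yaml.safe_dump({"c1": self.c1, "c2": self.c2, "c3": self.c3})

    @classmethod
    def from_yaml(cls, text: str) -> "OxygenResponseParams":
        d = yaml.safe_load(text)
        return cls(c1=float(d["c1"]), c2=float(d["c2"]), c3=float(d["c3"]))


#: Default 2 MeV electron response parameters (also used for photon beams,
#: whose dose is deposited by secondary electrons).
DEFAULT_RESPONSE = OxygenResponseParams(c1=8.334, c2=15.99, c3=5.67)


@dataclass(frozen=True)
class DamageCoefficients:
    """Energy-tabulated linear-transform coefficients.

    Each row maps an electron kinetic energy y (MeV) to the damage scale
    a(y) and the hypoxic damage floor b(y) (DSB-class lesions per cell per
    Gbp per Gy).  Lesion yield at energy y is a(y) * F_sat(pO2) + b(y) with
    piecewise-linear interpolation of a and b in energy; no extrapolation.
    """

    energies: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "energies", np.asarray(self.energies, dtype=float))
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if not (self.energies.size == self.a.size == self.b.size):
            raise ConfigurationError("energies, a and b must have equal length")
        if self.energies.size == 0:
            raise ConfigurationError("coefficient table is empty")
        if self.energies.size > 1 and not np.all(np.diff(self.energies) > 0):
            raise ConfigurationError("energies must be strictly increasing")
        if np.any(self.a < 0) or np.any(self.b <= 0):
            raise ConfigurationError("need a >= 0 and b > 0 everywhere")

    @classmethod
    def from_csv(cls, path) -> "DamageCoefficients":
        df = pd.read_csv(path)
        return cls(df["energy_mev"].to_numpy(), df["a"].to_numpy(), df["b"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"energy_mev": self.energies, "a": self.a, "b": self.b}
        ).to_csv(path, index=False)


def saturation_response(o2, params: SaturationParams):
    """Saturable fixation response pO2 / (q1 + q2*pO2).

    Rises from 0 at full hypoxia to the site capacity m_t as pO2 -> inf;
    equals m_t/2 at pO2 = k_d.
    """
    o2 = np.asarray(o2, dtype=float)
    if np.any(o2 < 0):
        raise ValueError("pO2 must be >= 0")
    out = o2 / (params.q1 + params.q2 * o2)
    return float(out) if out.ndim == 0 else out


def oxygen_response(o2, params: OxygenResponseParams = DEFAULT_RESPONSE):
    """Lesion yield per Gy at partial pressure ``o2`` (Torr).

    Evaluates (c1*o2 + c2) / (o2 + c3); accepts scalars or arrays.
    """
    o2 = np.asarray(o2, dtype=float)
    if np.any(o2 < 0):
        raise ValueError("pO2 must be >= 0")
    out = (params.c1 * o2 + params.c2) / (o2 + params.c3)
    return float(out) if out.ndim == 0 else out


def damage_yield(
    energy: float,
    o2: float,
    coeffs: DamageCoefficients,
    sat: SaturationParams,
) -> float:
    """Lesion yield per Gy at electron energy ``energy`` (MeV) and pO2 ``o2``.

    a and b are interpolated linearly in the coefficient table; querying
    outside the tabulated span raises (no extrapolation is attempted because
    no functional form in energy is assumed).
    """
    e = coeffs.energies
    if energy < e[0] or energy > e[-1]:
        raise ValueError(
            f"energy {energy} MeV outside tabulated span [{e[0]}, {e[-1]}]"
        )
    a = float(np.interp(energy, e, coeffs.a))
    b = float(np.interp(energy, e, coeffs.b))
    return a * saturation_response(o2, sat) + b


def spectrum_weighted_response(
    spectrum: Sequence[tuple[float, float]],
    o2: float,
    coeffs: DamageCoefficients,
    sat: SaturationParams,
) -> float:
    """Fluence-weighted mean lesion yield over an energy spectrum.

    ``spectrum`` is a sequence of (energy MeV, weight) pairs with
    non-negative weights summing to a positive total.
    """
    if len(spectrum) == 0:
        raise ValueError("spectrum is empty")
    energies, weights = zip(*spectrum)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be >= 0 with positive sum")
    yields = np.array([damage_yield(e, o2, coeffs, sat) for e in energies])
    return float(np.sum(w * yields) / w.sum())


def _response_model(o2, c1, c2, c3):
    return (c1 * o2 + c2) / (o2 + c3)


def fit_response_params(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
) -> tuple[OxygenResponseParams, dict]:
    """Least-squares fit of the rational response to (pO2, yield) points.

    Parameters
    ----------
    points
        Sequence of (o2_torr, yield) pairs or a DataFrame with columns
        ``o2_torr`` and ``yield``.  At least 4 distinct pO2 values are
        required; including a point near 0 anchors the hypoxic floor.

    Returns
    -------
    (params, diagnostics) where diagnostics contains the residual norm,
    per-parameter standard errors and a ``flat`` flag raised when the fitted
    response is degenerate (c1*c3 ~= c2, i.e. no oxygen dependence).

    Raises
    ------
    FitError
        If the data are degenerate or the optimiser fails to converge.
    """
    if isinstance(points, pd.DataFrame):
        o2 = points["o2_torr"].to_numpy(dtype=float)
        y = points["yield"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        o2, y = arr[:, 0], arr[:, 1]
    if np.unique(o2).size < 4:
        raise FitError(
            "need at least 4 distinct pO2 values",
            {"n_distinct": int(np.unique(o2).size)},
        )
    # Robust initialisation for saturation shapes: asymptote from the max,
    # floor from the min, half-saturation from mid-range pO2.
    y_min, y_max = float(np.min(y)), float(np.max(y))
    c3_0 = max(float(np.median(o2)), 1e-3)
    p0 = [max(y_max, 1e-6), max(c3_0 * y_min, 1e-6), c3_0]
    try:
        popt, pcov = optimize.curve_fit(
            _response_model,
            o2,
            y,
            p0=p0,
            bounds=(0.0, np.inf),
            maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"response fit did not converge: {exc}", {"p0": p0}) from exc
    resid = y - _response_model(o2, *popt)
    stderr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    c1, c2, c3 = (float(v) for v in popt)
    span = abs(c1 * c3 - c2)
    scale = max(abs(c1 * c3), abs(c2), 1e-30)
    diagnostics = {
        "residual_norm": float(np.linalg.norm(resid)),
        "stderr": {"c1": float(stderr[0]), "c2": float(stderr[1]), "c3": float(stderr[2])},
        "flat": bool(span / scale < 1e-6),
        "n_points": int(o2.size),
    }
    # A noisy flat dataset can land a hair under the monotonicity constraint;
    # snap it to the boundary rather than failing construction.
    if c1 * c3 < c2:
        c2 = c1 * c3
    return OxygenResponseParams(c1=c1, c2=c2, c3=c3), diagnostics


def read_response_table(path) -> pd.DataFrame:
    """Read a (o2_torr, yield) CSV table."""
    df = pd.read_csv(path)
    missing = {"o2_torr", "yield"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"response table missing columns: {sorted(missing)}")
    return df
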