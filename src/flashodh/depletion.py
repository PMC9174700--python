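"""Radiolytic oxygen-depletion trajectory models.

Two depletion models are provided:

* the empirical linear (Whillans-Rauth) model, a constant depletion rate R
  in Torr/Gy clamped at full hypoxia:  pO2(d) = max(pO2_0 - R*d, 0).
  Observed conventional-dose-rate values of R are 0.21-0.42 Torr/Gy;
  effective ultra-high-dose-rate values fitted to pulsed cell experiments
  are an order of magnitude steeper (~15 Torr/Gy).

* the second-order (Ling) kinetics model, in which oxygen binds to
  radiation-induced species.  With initial concentration x0, induced-species
  yield G per Gy, delivered dose D and binding rate lambda (per
  Torr-equivalent per ns), the concentration solves

      dx/dt = -lambda * x * (x + G*D - x0)

  whose closed form is evaluated here in an overflow-safe arrangement, with
  the analytic equal-rate limit x0 / (1 + lambda*x0*t) taken when
  G*D ~= x0.  Depletion may be incomplete: the t -> inf residual is
  max(x0 - G*D, 0).

Both models are reduced to a common piecewise-linear
:class:`DepletionTrajectory` mapping cumulative dose to instantaneous pO2,
which is what histogram construction consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FlashOdhError

__all__ = [
    "LinearDepletionModel",
    "LingDepletionModel",
    "DepletionTrajectory",
    "linear_o2_at_dose",
    "linear_trajectory",
    "ling_o2_at_time",
    "ling_residual",
    "ling_trajectory",
]

#: Relative tolerance below which |G*D - x0| is treated as the singular
#: equal-rate case of the second-order model (avoids 0/0 cancellation).
_LING_SINGULAR_RTOL = 1e-9


@dataclass(frozen=True)
class LinearDepletionModel:
    """Constant-rate depletion: ``rate_r`` Torr removed per Gy delivered."""

    o2_0: float
    rate_r: float

    def __post_init__(self):
        if self.o2_0 < 0 or self.rate_r < 0:
            raise ConfigurationError(
                f"o2_0 and rate_r must be >= 0, got {self.o2_0}, {self.rate_r}"
            )


@dataclass(frozen=True)
class LingDepletionModel:
    """Second-order binding of oxygen to radiation-induced species."""

    o2_0: float
    g_yield: float  # induced-species concentration per Gy (Torr-equivalent)
    dose_d: float   # delivered dose, Gy
    lam: float      # binding rate, per Torr-equivalent per ns

    def __post_init__(self):
        for name in ("o2_0", "g_yield", "dose_d", "lam"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DepletionTrajectory:
    """Piecewise-linear map from cumulative dose (Gy) to pO2 (Torr).

    Breakpoint doses are non-decreasing and pO2 is non-increasing and
    non-negative along the trajectory; values between breakpoints are linear
    interpolants.
    """

    doses: np.ndarray
    o2: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        object.__setattr__(self, "o2", np.asarray(self.o2, dtype=float))
        if self.doses.size != self.o2.size or self.doses.size < 2:
            raise ConfigurationError("trajectory needs >= 2 matched breakpoints")
        if np.any(np.diff(self.doses) < 0):
            raise ConfigurationError("breakpoint doses must be non-decreasing")
        if np.any(np.diff(self.o2) > 1e-12):
            raise FlashOdhError("trajectory pO2 must be non-increasing")
        if np.any(self.o2 < 0):
            raise FlashOdhError("trajectory pO2 must be >= 0")

    @property
    def total_dose(self) -> float:
        return float(self.doses[-1] - self.doses[0])

    def o2_at(self, d):
        """Interpolated pO2 at cumulative dose ``d``."""
        out = np.interp(d, self.doses, self.o2)
        return float(out) if np.ndim(d) == 0 else out

    def shifted(self, dose_offset: float) -> "DepletionTrajectory":
        return DepletionTrajectory(self.doses + dose_offset, self.o2.copy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"cum_dose_gy": self.doses, "o2_torr": self.o2}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "DepletionTrajectory":
        df = pd.read_csv(path)
        return cls(df["cum_dose_gy"].to_numpy(), df["o2_torr"].to_numpy())


def linear_o2_at_dose(model: LinearDepletionModel, d):
    """pO2 after delivering ``d`` Gy under constant-rate depletion."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    out = np.maximum(model.o2_0 - model.rate_r * d, 0.0)
    return float(out) if out.ndim == 0 else out


def linear_trajectory(model: LinearDepletionModel, total_dose: float) -> DepletionTrajectory:
    """Exact piecewise-linear trajectory for the constant-rate model.

    Breakpoints at dose 0, at the hypoxia-onset dose o2_0/rate_r when it is
    reached within ``total_dose``, and at ``total_dose``.
    """
    if total_dose <= 0:
        raise ValueError(f"total_dose must be > 0, got {total_dose}")
    if model.rate_r == 0 or model.o2_0 == 0:
        return DepletionTrajectory([0.0, total_dose], [model.o2_0, model.o2_0])
    d_hyp = model.o2_0 / model.rate_r
    if d_hyp < total_dose:
        return DepletionTrajectory(
            [0.0, d_hyp, total_dose], [model.o2_0, 0.0, 0.0]
        )
    return DepletionTrajectory(
        [0.0, total_dose], [model.o2_0, model.o2_0 - model.rate_r * total_dose]
    )


def ling_o2_at_time(model: LingDepletionModel, t):
    """Closed-form second-order depletion pO2 at time ``t`` (ns).

    Uses the analytic equal-rate limit when G*D ~= x0 and an exponent-sign
    split so that neither branch overflows at large t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    x0 = model.o2_0
    gd = model.g_yield * model.dose_d
    lam = model.lam
    if x0 == 0.0:
        out = np.zeros_like(t)
        return float(out) if out.ndim == 0 else out
    if abs(gd - x0) < _LING_SINGULAR_RTOL * max(gd, x0):
        out = x0 / (1.0 + lam * x0 * t)
        return float(out) if out.ndim == 0 else out
    k = np.clip(lam * (x0 - gd) * t, -700.0, 700.0)
    # x(t) = x0*(gd - x0)*e^k / (gd - x0*e^k); divide through by e^k when
    # k > 0 so the evaluated exponential always decays.
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(
            k > 0,
            x0 * (gd - x0) / (gd * np.exp(-np.abs(k)) - x0),
            x0 * (gd - x0) * np.exp(-np.abs(k)) / (gd - x0 * np.exp(-np.abs(k))),
        )
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def ling_residual(model: LingDepletionModel) -> float:
    """Residual oxygen left as t -> inf: max(x0 - G*D, 0)."""
    return max(model.o2_0 - model.g_yield * model.dose_d, 0.0)


def ling_trajectory(
    model: LingDepletionModel, pulse_length: float, n_steps: int = 256
) -> DepletionTrajectory:
    """Sampled dose-domain trajectory for one rectangular pulse.

    The in-pulse dose rate is assumed constant, so time t in [0, L] maps to
    cumulative dose d = D * t / L.  The closed form is sampled at ``n_steps``
    points and returned as a piecewise-linear trajectory.
    """
    if pulse_length <= 0:
        raise ValueError("pulse_length must be > 0")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    times = np.linspace(0.0, pulse_length, n_steps)
    o2 = ling_o2_at_time(model, times)
    # Guard against non-monotone float noise before the trajectory invariant.
    o2 = np.minimum.accumulate(o2)
    doses = model.dose_d * times / pulse_length
    return DepletionTrajectory(doses, o2)
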