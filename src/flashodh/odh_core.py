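"""Pulses, pulse trains and oxygen-dose-histogram construction and algebra.

The oxygen dose histogram (ODH) is the central abstraction: delivered dose
(Gy) binned by the instantaneous pO2 (Torr) at which it was deposited.  Its
area is the total delivered dose and — unlike the inverse curve of pO2
versus cumulative dose (the DOH, i.e. a depletion trajectory) — ODHs are
additive, so multi-pulse deliveries compose by histogram addition and a
train of identical pulses with full re-oxygenation is simply the
single-pulse histogram scaled by the pulse count.

Bins are left-closed right-open [lo, hi) with the lowest edge at exactly 0,
so fully hypoxic dose occupies the first bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .depletion import (
    DepletionTrajectory,
    LinearDepletionModel,
    LingDepletionModel,
    linear_trajectory,
    ling_trajectory,
)
from .errors import ConfigurationError
from .units import GY_PER_CGY, NS_PER_MS

__all__ = [
    "Pulse",
    "PulseTrain",
    "OxygenDoseHistogram",
    "DEFAULT_BIN_WIDTH",
    "pulse_dose",
    "dose_per_pulse",
    "odh_from_trajectory",
    "add",
    "scale",
    "compose_train",
]

#: Default pO2 bin width, Torr.
DEFAULT_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class Pulse:
    """A single beam pulse of length ``length_l`` ns.

    ``rate_shape`` is either a constant instantaneous dose rate in cGy/ns or
    a tabulated (times_ns, rates_cgy_per_ns) pair covering [0, length_l].
    """

    length_l: float
    rate_shape: Union[float, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        if self.length_l <= 0:
            raise ConfigurationError(f"pulse length must be > 0, got {self.length_l}")
        if isinstance(self.rate_shape, (int, float)):
            if self.rate_shape < 0:
                raise ConfigurationError("dose rate must be >= 0")
        else:
            times, rates = (np.asarray(v, dtype=float) for v in self.rate_shape)
            if times.size != rates.size or times.size < 2:
                raise ConfigurationError("tabulated shape needs >= 2 matched samples")
            if np.any(np.diff(times) <= 0):
                raise ConfigurationError("shape times must be strictly increasing")
            if np.any(rates < 0):
                raise ConfigurationError("dose rate must be >= 0 everywhere")
            object.__setattr__(self, "rate_shape", (times, rates))

    @classmethod
    def rectangular(cls, length_ns: float, rate_cgy_per_ns: float) -> "Pulse":
        return cls(length_l=length_ns, rate_shape=float(rate_cgy_per_ns))

    @classmethod
    def from_dose(cls, length_ns: float, dose_gy: float) -> "Pulse":
        """Rectangular pulse delivering ``dose_gy`` over ``length_ns``."""
        if dose_gy < 0:
            raise ConfigurationError("dose must be >= 0")
        return cls.rectangular(length_ns, dose_gy / GY_PER_CGY / length_ns)


@dataclass(frozen=True)
class PulseTrain:
    """``count`` repetitions of ``pulse``, pulse starts ``period`` ms apart.

    ``reoxygenation`` models the tissue between pulses: "full" restores the
    initial pO2, "none" continues depleting from the previous pulse's end
    level, and "partial" restores a fraction ``fraction`` of the deficit.
    """

    pulse: Pulse
    count: int = 1
    period: float = 10.0
    reoxygenation: str = "full"
    fraction: float = 1.0

    def __post_init__(self):
        if self.count < 1:
            raise ConfigurationError("count must be >= 1")
        if self.reoxygenation not in ("full", "none", "partial"):
            raise ConfigurationError(
                f"reoxygenation must be full|none|partial, got {self.reoxygenation!r}"
            )
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError("fraction must be in [0, 1]")
        if self.count > 1 and self.period * NS_PER_MS < self.pulse.length_l:
            raise ConfigurationError("period must be >= pulse length")

    @property
    def reox_fraction(self) -> float:
        return {"full": 1.0, "none": 0.0, "partial": self.fraction}[self.reoxygenation]


class OxygenDoseHistogram:
    """Dose (Gy) binned by the pO2 (Torr) at which it was delivered."""

    def __init__(self, edges, doses):
        edges = np.asarray(edges, dtype=float)
        doses = np.asarray(doses, dtype=float)
        if edges.ndim != 1 or doses.ndim != 1 or edges.size != doses.size + 1:
            raise ConfigurationError("need len(edges) == len(doses) + 1")
        if edges[0] != 0.0:
            raise ConfigurationError("lowest pO2 edge must be exactly 0")
        if np.any(np.diff(edges) <= 0):
            raise ConfigurationError("edges must be strictly increasing")
        if np.any(doses < -1e-15 * max(doses.sum(), 1.0)):
            raise ConfigurationError("bin doses must be >= 0")
        self.edges = edges
        self.doses = np.maximum(doses, 0.0)

    @property
    def total_dose(self) -> float:
        return float(self.doses.sum())

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OxygenDoseHistogram)
            and self.edges.shape == other.edges.shape
            and np.array_equal(self.edges, other.edges)
            and np.array_equal(self.doses, other.doses)
        )

    def __add__(self, other: "OxygenDoseHistogram") -> "OxygenDoseHistogram":
        return add(self, other)

    def __mul__(self, k: float) -> "OxygenDoseHistogram":
        return scale(self, k)

    __rmul__ = __mul__

    def __repr__(self) -> str:
        return (
            f"OxygenDoseHistogram({self.doses.size} bins, "
            f"[0, {self.edges[-1]:g}) Torr, {self.total_dose:g} Gy)"
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "o2_lo_torr": self.edges[:-1],
                "o2_hi_torr": self.edges[1:],
                "dose_gy": self.doses,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OxygenDoseHistogram":
        df = pd.read_csv(path)
        edges = np.append(df["o2_lo_torr"].to_numpy(), df["o2_hi_torr"].to_numpy()[-1])
        return cls(edges, df["dose_gy"].to_numpy())

    @classmethod
    def empty(cls, bin_width: float = DEFAULT_BIN_WIDTH) -> "OxygenDoseHistogram":
        return cls([0.0, bin_width], [0.0])


def pulse_dose(pulse: Pulse) -> float:
    """Total dose of one pulse in Gy (area under the dose-rate curve).

    Rectangular pulses use the exact product L * rate; tabulated shapes use
    trapezoid quadrature.
    """
    if isinstance(pulse.rate_shape, (int, float)):
        return pulse.length_l * float(pulse.rate_shape) * GY_PER_CGY
    times, rates = pulse.rate_shape
    return float(np.trapezoid(rates, times)) * GY_PER_CGY


def dose_per_pulse(mean_rate: float, prf: float) -> float:
    """Dose per pulse (Gy) from a mean dose rate (Gy/s) and a PRF (Hz)."""
    if prf <= 0:
        raise ValueError(f"pulse repetition frequency must be > 0, got {prf}")
    return mean_rate / prf


def _edges_for(max_o2: float, bin_width: float) -> np.ndarray:
    # One bin beyond max_o2 so a constant trajectory sitting exactly on the
    # top value still falls inside a right-open bin.
    n = int(math.floor(max_o2 / bin_width + 1e-12)) + 1
    return np.arange(n + 1, dtype=float) * bin_width


def odh_from_trajectory(
    traj: DepletionTrajectory,
    bin_width: float = DEFAULT_BIN_WIDTH,
    edges: Optional[np.ndarray] = None,
) -> OxygenDoseHistogram:
    """Bin a depletion trajectory's dose by instantaneous pO2.

    Dose is integrated exactly over each piecewise-linear trajectory segment:
    within a segment the dose deposited per unit pO2 is constant, so each bin
    receives (overlap of its pO2 interval with the segment's) * density.  For
    a pure linear trajectory every fully traversed bin therefore receives
    bin_width / rate Gy and the hypoxic bin the remainder.
    """
    if traj.total_dose <= 0:
        raise ValueError("trajectory must span positive dose")
    max_o2 = float(traj.o2.max())
    if edges is None:
        if bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        edges = _edges_for(max_o2, bin_width)
    else:
        edges = np.asarray(edges, dtype=float)
        if edges[0] != 0.0 or edges[-1] <= max_o2:
            raise ConfigurationError(
                "explicit edges must start at 0 and extend beyond the "
                f"trajectory maximum ({max_o2} Torr)"
            )
    doses = np.zeros(edges.size - 1)
    lo, hi = edges[:-1], edges[1:]
    for i in range(traj.doses.size - 1):
        d0, d1 = traj.doses[i], traj.doses[i + 1]
        if d1 <= d0:
            continue
        o0, o1 = traj.o2[i], traj.o2[i + 1]
        if o0 == o1:
            idx = int(np.searchsorted(edges, o0, side="right")) - 1
            idx = min(max(idx, 0), doses.size - 1)
            doses[idx] += d1 - d0
        else:
            density = (d1 - d0) / (o0 - o1)  # Gy per Torr within this segment
            overlap = np.clip(np.minimum(hi, o0) - np.maximum(lo, o1), 0.0, None)
            doses += overlap * density
    return OxygenDoseHistogram(edges, doses)


def add(a: OxygenDoseHistogram, b: OxygenDoseHistogram) -> OxygenDoseHistogram:
    """Bin-wise sum after rebinning both operands to the union edge grid.

    Rebinning is mass preserving, assuming piecewise-constant dose density
    within each source bin.
    """
    if a.edges.shape == b.edges.shape and np.array_equal(a.edges, b.edges):
        return OxygenDoseHistogram(a.edges, a.doses + b.doses)
    edges = np.union1d(a.edges, b.edges)
    return OxygenDoseHistogram(
        edges, _rebin(a, edges) + _rebin(b, edges)
    )


def _rebin(odh: OxygenDoseHistogram, edges: np.ndarray) -> np.ndarray:
    lo, hi = edges[:-1], edges[1:]
    out = np.zeros(lo.size)
    for src_lo, src_hi, dose in zip(odh.edges[:-1], odh.edges[1:], odh.doses):
        if dose == 0.0:
            continue
        overlap = np.clip(np.minimum(hi, src_hi) - np.maximum(lo, src_lo), 0.0, None)
        width = src_hi - src_lo
        out += dose * overlap / width
    # The union grid may end below a source bin's top edge only if edges do
    # not cover it; union1d of both edge sets always covers, so mass is kept.
    return out


def scale(odh: OxygenDoseHistogram, k: float) -> OxygenDoseHistogram:
    """Multiply all bin doses by ``k`` > 0."""
    if k <= 0:
        raise ValueError(f"scale factor must be > 0, got {k}")
    return OxygenDoseHistogram(odh.edges, odh.doses * k)


def _single_pulse_trajectory(
    model: Union[LinearDepletionModel, LingDepletionModel],
    pulse: Pulse,
    o2_start: float,
    dpp: float,
    n_steps: int,
) -> DepletionTrajectory:
    if isinstance(model, LinearDepletionModel):
        return linear_trajectory(
            LinearDepletionModel(o2_0=o2_start, rate_r=model.rate_r), dpp
        )
    m = LingDepletionModel(
        o2_0=o2_start, g_yield=model.g_yield, dose_d=dpp, lam=model.lam
    )
    return ling_trajectory(m, pulse.length_l, n_steps=n_steps)


def compose_train(
    train: PulseTrain,
    model: Union[LinearDepletionModel, LingDepletionModel],
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_steps: int = 256,
) -> OxygenDoseHistogram:
    """ODH of a whole pulse train under the model's depletion kinetics.

    With full re-oxygenation every pulse has an identical oxygen signature,
    so the result is the single-pulse ODH scaled by the pulse count.  With
    none/partial re-oxygenation pulse i+1 starts at
    o2_end + f * (o2_0 - o2_end) and the per-pulse histograms are added.
    """
    dpp = pulse_dose(train.pulse)
    if dpp <= 0:
        raise ValueError("pulse dose must be > 0")
    edges = _edges_for(model.o2_0, bin_width)
    f = train.reox_fraction
    if f == 1.0:
        traj = _single_pulse_trajectory(model, train.pulse, model.o2_0, dpp, n_steps)
        single = odh_from_trajectory(traj, edges=edges)
        return scale(single, train.count) if train.count > 1 else single
    total = OxygenDoseHistogram(edges, np.zeros(edges.size - 1))
    o2_start = model.o2_0
    for _ in range(train.count):
        traj = _single_pulse_trajectory(model, train.pulse, o2_start, dpp, n_steps)
        total = add(total, odh_from_trajectory(traj, edges=edges))
        o2_end = float(traj.o2[-1])
        o2_start = o2_end + f * (model.o2_0 - o2_end)
    return total
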