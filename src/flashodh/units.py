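"""Unit conventions and converters.

Internal canonical units are Torr (partial oxygen pressure), Gy (dose) and
ns (time).  Boundary quantities arrive in the units practitioners quote:
mean dose rates in Gy/s, pulse periods in ms, instantaneous in-pulse dose
rates in cGy/ns (1 cGy/ns = 1e7 Gy/s).
"""

from __future__ import annotations

#: Atmospheric pressure in Torr; 100% O2 at 1 atm corresponds to 760 Torr,
#: so the common "20% oxygen" lab condition is ~152 Torr pO2.
TORR_PER_ATM = 760.0

#: 1 cGy/ns expressed in Gy/s.
GY_PER_S_PER_CGY_PER_NS = 1.0e7

NS_PER_MS = 1.0e6
GY_PER_CGY = 0.01


def torr_from_percent(percent: float) -> float:
    """Convert an oxygen fraction in percent of 1 atm to Torr (20% -> 152)."""
    if percent < 0:
        raise ValueError(f"oxygen percentage must be >= 0, got {percent}")
    return percent / 100.0 * TORR_PER_ATM


def percent_from_torr(torr: float) -> float:
    """Convert a pO2 in Torr to percent of one atmosphere."""
    if torr < 0:
        raise ValueError(f"pO2 must be >= 0, got {torr}")
    return torr / TORR_PER_ATM * 100.0


def gy_per_s_from_cgy_per_ns(rate: float) -> float:
    return rate * GY_PER_S_PER_CGY_PER_NS


def cgy_per_ns_from_gy_per_s(rate: float) -> float:
    return rate / GY_PER_S_PER_CGY_PER_NS
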