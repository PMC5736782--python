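"""Phospholipid membrane affinity: IAM chromatography and MLV partitioning.

LogK(IAM) is the log10 capacity factor on an immobilised artificial membrane
column, ``log10((Tr - T0)/T0)``, where ``Tr`` is the compound's theoretical
retention time in 100% water and ``T0`` the solvent front (75 s by default).
``Tr`` is obtained by linear extrapolation of the retention times measured at
10/20/30% (v/v) organic modifier down to 0% organic.

MLV partitioning is the fraction of compound lost from the aqueous phase into
multi-lamellar liposome vesicles at equilibrium, ``(C0 - Cs)/C0``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "IamMeasurement",
    "MlvMeasurement",
    "extrapolate_retention",
    "logk_iam",
    "logk_iam_from_measurement",
    "mlv_partition",
]


@dataclass(frozen=True)
class IamMeasurement:
    """Retention times (s) keyed by organic-modifier fraction (% v/v)."""

    retention_times: Mapping[float, float]
    t0: float = 75.0  # solvent front, seconds

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("solvent front t0 must be positive")
        if len(self.retention_times) < 2:
            raise ValueError("need retention times at >= 2 organic fractions")
        for frac, tr in self.retention_times.items():
            if tr <= self.t0:
                raise ValueError(
                    f"retention time {tr:g}s at {frac:g}% organic does not "
                    f"exceed the solvent front ({self.t0:g}s)"
                )


def extrapolate_retention(m: IamMeasurement, space: str = "time") -> float:
    """Theoretical retention time (s) in 100% water.

    ``space="time"`` (the default) regresses the retention time itself on the
    organic fraction and returns the intercept.  ``space="logk"`` regresses the
    log10 capacity factor instead -- the common chromatographic convention --
    and converts the intercept back to a retention time.  Raises if the
    extrapolated retention does not clear the solvent front (LogK undefined).
    """
    fractions = np.array(sorted(m.retention_times), dtype=float)
    tr = np.array([m.retention_times[f] for f in fractions], dtype=float)
    if space == "time":
        slope, intercept = np.polyfit(fractions, tr, 1)
        tr_water = float(intercept)
    elif space == "logk":
        logk = np.log10((tr - m.t0) / m.t0)
        slope, intercept = np.polyfit(fractions, logk, 1)
        tr_water = float(m.t0 * (1.0 + 10.0 ** intercept))
    else:
        raise ValueError(f"unknown extrapolation space {space!r}")
    if tr_water <= m.t0:
        raise ValueError(
            f"extrapolated retention {tr_water:g}s does not exceed the solvent "
            f"front ({m.t0:g}s): LogK(IAM) is undefined"
        )
    return tr_water


def logk_iam(tr_water: float, t0: float) -> float:
    """``log10((Tr - T0)/T0)`` for Tr extrapolated to 100% water."""
    if t0 <= 0 or tr_water <= t0:
        raise ValueError("requires tr_water > t0 > 0")
    return math.log10((tr_water - t0) / t0)


def logk_iam_from_measurement(m: IamMeasurement, space: str = "time") -> float:
    return logk_iam(extrapolate_retention(m, space=space), m.t0)


@dataclass(frozen=True)
class MlvMeasurement:
    """Initial (c0) and post-equilibration supernatant (cs) concentrations, ug/mL."""

    c0: float
    cs: float

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("initial concentration c0 must be positive")
        if not 0 <= self.cs <= self.c0:
            raise ValueError("supernatant concentration must lie in [0, c0]")


def mlv_partition(m: MlvMeasurement) -> float:
    """Fraction partitioned into the vesicles: ``(c0 - cs)/c0`` in [0, 1]."""
    return (m.c0 - m.cs) / m.c0
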