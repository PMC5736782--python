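"""Ussing-chamber intestinal permeability.

An ileal segment separates a donor (mucosal) and receiver (serosal) chamber,
3 mL each, with 0.12 cm^2 of tissue exposed.  Serial 1 mL receiver samples are
replaced with blank buffer over 180 min, so cumulative transported mass uses
the same serial-sampling correction as the IPML reservoir.  The apparent
permeability coefficient is

    Papp = (dM/dt) / (A * C0)        [cm/s]

with dM/dt the slope (nmol/s) of cumulative serosal amount vs time from a
free-intercept ordinary least-squares line over the whole experiment, A the
exposed area (cm^2) and C0 the initial donor concentration (nmol/mL == nmol/cm^3).

Tissue-integrity QC: segments with an initial transepithelial electrical
resistance (TEER) below 80 Ohm*cm^2, or whose TEER falls by more than 10%
during the experiment, are excluded.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ipml_kinetics import QCResult, Verdict, sampling_corrected_mass

__all__ = [
    "Genotype",
    "UssingExperiment",
    "PappResult",
    "ussing_qc",
    "papp",
    "ko_wt_ratio",
]


class Genotype(str, enum.Enum):
    WT = "WT"  # Mdr1a/1b (+/+)
    KO = "KO"  # Mdr1a/1b (-/-)


@dataclass(frozen=True)
class UssingExperiment:
    times: np.ndarray  # minutes, ascending, within [0, 180]
    serosal_concentrations: np.ndarray  # nmol/mL, pre-replacement
    donor_c0: float  # nmol/mL
    chamber_volume: float = 3.0  # mL
    sample_volume: float = 1.0  # mL
    exposed_area: float = 0.12  # cm^2
    teer_initial: float | None = None  # Ohm*cm^2
    teer_final: float | None = None
    genotype: Genotype | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self,
            "serosal_concentrations",
            np.asarray(self.serosal_concentrations, dtype=float),
        )
        t, c = self.times, self.serosal_concentrations
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and aligned")
        if len(t) and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be ascending and non-negative")
        if self.exposed_area <= 0:
            raise ValueError("exposed area must be positive")
        if self.donor_c0 <= 0:
            raise ValueError("donor concentration must be positive")
        if not 0 < self.sample_volume < self.chamber_volume:
            raise ValueError("sample volume must lie in (0, chamber volume)")


def ussing_qc(e: UssingExperiment) -> QCResult:
    """TEER integrity verdict: exclude on initial TEER < 80 or a >10% decline."""
    reasons: list[str] = []
    if e.teer_initial is not None and e.teer_initial < 80.0:
        reasons.append(
            f"initial TEER {e.teer_initial:g} Ohm*cm^2 below the 80 Ohm*cm^2 floor"
        )
    if e.teer_initial is not None and e.teer_final is not None:
        decline = (e.teer_initial - e.teer_final) / e.teer_initial
        if decline > 0.10:
            reasons.append(f"TEER declined {100 * decline:.1f}% (> 10%) during the run")
    verdict = Verdict.EXCLUDE if reasons else Verdict.KEEP
    return QCResult(verdict=verdict, reasons=tuple(reasons))


@dataclass(frozen=True)
class PappResult:
    papp: float  # cm/s
    slope_nmol_per_s: float
    r_squared: float
    negative_slope: bool = False


def papp(e: UssingExperiment) -> PappResult:
    """Apparent permeability from the serosal accumulation series."""
    if len(e.times) < 3:
        raise ValueError("need at least 3 samples to estimate the transport rate")
    mass = sampling_corrected_mass(
        e.serosal_concentrations, e.chamber_volume, e.sample_volume
    )
    if np.allclose(mass, mass[0]):
        slope_min, r2 = 0.0, 0.0
    else:
        fit = stats.linregress(e.times, mass)
        slope_min = float(fit.slope)  # nmol/min
        r2 = float(fit.rvalue**2)
    slope_s = slope_min / 60.0
    return PappResult(
        papp=slope_s / (e.exposed_area * e.donor_c0),
        slope_nmol_per_s=slope_s,
        r_squared=r2,
        negative_slope=slope_s < 0,
    )


def ko_wt_ratio(papp_ko: float, papp_wt: float) -> float:
    """Knockout:wild-type permeability fold-change (full precision)."""
    if papp_wt <= 0:
        raise ValueError("wild-type Papp must be positive")
    return papp_ko / papp_wt
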