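"""Michaelis-Menten kinetics of transporter-stimulated ATPase activity.

Membranes constituted with an ABC transporter (human MDR1, mouse Mdr1a/Mdr1b,
mouse Bcrp) hydrolyse ATP when a substrate engages the transporter.  The rate v
at substrate concentration S follows ``v = Vmax * S / (Km + S)``; the assay
concentration range is 0-300 uM.  ``Vmax/Km`` (1/min) summarises catalytic
efficiency.  The assay does not distinguish substrates from inhibitors; it
ranks interaction kinetics against a given membrane model.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["Membrane", "AtpaseCurve", "MMFit", "fit_mm", "flag_nonreactive"]


class Membrane(str, enum.Enum):
    MDR1 = "MDR1"
    Mdr1a = "Mdr1a"
    Mdr1b = "Mdr1b"
    Bcrp = "Bcrp"


@dataclass(frozen=True)
class AtpaseCurve:
    """Rate-concentration data for one compound against one membrane."""

    concentrations: np.ndarray  # uM
    rates: np.ndarray  # uM/min
    membrane: Membrane | None = None
    compound: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations", np.asarray(self.concentrations, dtype=float)
        )
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        s, v = self.concentrations, self.rates
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("concentrations and rates must be 1-D and aligned")
        if np.any(s < 0):
            raise ValueError("concentrations must be non-negative")
        if len(np.unique(s)) < 4:
            raise ValueError("need at least 4 distinct concentrations")
        if not np.all(np.isfinite(v)):
            raise ValueError("rates must be finite")


@dataclass(frozen=True)
class MMFit:
    km: float  # uM
    vmax: float  # uM/min
    km_ci: tuple[float, float]
    vmax_ci: tuple[float, float]
    rss: float

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency Vmax/Km (1/min)."""
        return self.vmax / self.km

    def predict(self, s: np.ndarray | float) -> np.ndarray | float:
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


def fit_mm(curve: AtpaseCurve, ci_level: float = 0.95) -> MMFit:
    """Least-squares Michaelis-Menten fit with asymptotic confidence intervals.

    Initialised at Vmax0 = max rate and Km0 = concentration nearest half-max;
    both parameters constrained positive.
    """
    s, v = curve.concentrations, curve.rates
    if not np.any(s > 0):
        raise ValueError("need at least one non-zero concentration")
    vmax0 = max(float(np.max(v)), 1e-9)
    half = np.abs(v - vmax0 / 2.0)
    km0 = max(float(s[np.argmin(half)]), 1e-3)

    res = optimize.least_squares(
        lambda p: p[0] * s / (p[1] + s) - v,
        np.array([vmax0, km0]),
        bounds=([1e-12, 1e-9], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {res.message}")
    vmax_hat, km_hat = res.x
    rss = float(2.0 * res.cost)
    dof = len(s) - 2
    if dof > 0:
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac) * rss / dof
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.array([np.inf, np.inf])
        tq = stats.t.ppf(0.5 + ci_level / 2.0, dof)
    else:
        se = np.array([np.inf, np.inf])
        tq = np.inf
    vmax_ci = (float(vmax_hat - tq * se[0]), float(vmax_hat + tq * se[0]))
    km_ci = (float(km_hat - tq * se[1]), float(km_hat + tq * se[1]))
    return MMFit(
        km=float(km_hat), vmax=float(vmax_hat), km_ci=km_ci, vmax_ci=vmax_ci, rss=rss
    )


def flag_nonreactive(curve: AtpaseCurve, ci_level: float = 0.95) -> bool:
    """True when the curve shows no resolvable ATP turnover.

    A membrane/compound pair is flagged non-reactive when the fitted Vmax is
    indistinguishable from zero (its confidence interval covers 0) or when the
    fit fails outright.
    """
    if np.allclose(curve.rates, 0.0, atol=1e-12):
        return True
    try:
        fit = fit_mm(curve, ci_level=ci_level)
    except (RuntimeError, ValueError):
        return True
    return fit.vmax_ci[0] <= 0.0
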