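"""Seeded generators emulating the statistical structure of each assay.

Each generator is the exact inverse pair of its analysis stage: at zero noise
the consumer recovers the generating parameters to numerical precision, which
is the contract the unit tests exercise.  All randomness flows from a single
``numpy.random.default_rng(seed)`` stream per call; identical specs give
byte-identical outputs.

Default noise is multiplicative log-normal with a 5% coefficient of variation,
consistent with the bioanalytical precision the assays are run at.  The default
IPML design mirrors the experimental set-up: a 1.25 nmol airway dose (25 uL at
50 uM) with ~6% of the administered dose retained in the dosing device, a
10 mL recirculating reservoir sampled with 250 uL replacement draws at
2/5/10/15/20/30 min.  The Ussing design uses 1 mL draws from a 3 mL receiver
chamber over 180 min at a 50 nmol/mL donor concentration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .atpase_kinetics import AtpaseCurve, Membrane
from .core_io import CANONICAL_DESCRIPTORS, CompoundRecord, DescriptorMatrix, Group
from .ipml_kinetics import PerfusateProfile
from .ussing_permeability import Genotype, UssingExperiment

__all__ = [
    "IpmlSimSpec",
    "UssingSimSpec",
    "MMSimSpec",
    "DescriptorClassSpec",
    "gen_ipml_arm",
    "gen_ussing",
    "gen_mm_curves",
    "gen_descriptor_classes",
    "POLARITY_DESCRIPTORS",
]

#: Descriptors that define the polarity axis separating the two classes.
POLARITY_DESCRIPTORS = (
    "abraham_acidity",
    "abraham_basicity",
    "psa",
    "hbd",
    "hba",
    "hb_total",
)

#: Descriptors spanning the class-orthogonal "bulk/size" nuisance axis.
_SIZE_DESCRIPTORS = (
    "mw",
    "abraham_volume",
    "abraham_polarizability",
    "abraham_mri",
    "rotatable_bonds",
)

# Raw-scale location/spread per canonical descriptor, matching the magnitudes
# of the packaged descriptor fixture so generated tables look like real ones.
_RAW_MEAN = np.array(
    [1.8, 2.6, 0.8, 2.6, 4.3, 6.5, 10.8, 9.3, 3.7, 3.2, 106.0, 476.0, 2.9]
)
_RAW_SD = np.array(
    [1.4, 1.7, 0.5, 1.2, 2.6, 4.5, 5.6, 4.4, 1.2, 1.3, 56.0, 151.0, 0.9]
)

_INTEGER_IDX = [
    CANONICAL_DESCRIPTORS.index(n)
    for n in ("hbd", "hba", "hb_total", "rotatable_bonds")
]


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with the given CV."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return np.ones(size)
    s = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * s * s, s, size=size))


# ---------------------------------------------------------------------------
# IPML reservoir profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IpmlSimSpec:
    seed: int = 0
    n_replicates: int = 5
    cv: float = 0.05
    f: float = 0.26  # fraction of deposited dose absorbed at t -> inf
    ka: float = 0.1  # 1/min
    schedule: Sequence[float] = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    administered_nmol: float = 1.25
    device_fraction: float = 0.06
    reservoir_volume: float = 10.0
    sample_volume: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise ValueError("F must lie in (0, 1]")
        if self.ka <= 0:
            raise ValueError("Ka must be positive")
        if min(self.schedule) <= 0:
            raise ValueError("sampling schedule must start after t = 0")


def gen_ipml_arm(spec: IpmlSimSpec) -> list[PerfusateProfile]:
    """Simulate reservoir profiles by exact first-order transfer bookkeeping.

    Between samples the true absorbed mass ``D*F*(1 - exp(-Ka t))`` increments
    the well-mixed reservoir; each draw removes ``C_i * V_s`` and replaces it
    with blank perfusate.  Noise multiplies the measured concentrations only,
    never the underlying mass balance.
    """
    rng = np.random.default_rng(spec.seed)
    deposited = spec.administered_nmol * (1.0 - spec.device_fraction)
    device_residual = spec.administered_nmol - deposited
    times = np.asarray(spec.schedule, dtype=float)
    profiles = []
    for _ in range(spec.n_replicates):
        absorbed = deposited * spec.f * (1.0 - np.exp(-spec.ka * times))
        reservoir_mass = 0.0
        prev_absorbed = 0.0
        concs = np.empty_like(times)
        for i, a in enumerate(absorbed):
            reservoir_mass += a - prev_absorbed
            prev_absorbed = a
            concs[i] = reservoir_mass / spec.reservoir_volume
            reservoir_mass *= (
                spec.reservoir_volume - spec.sample_volume
            ) / spec.reservoir_volume
        noisy = concs * _noise_factors(rng, spec.cv, len(times))
        profiles.append(
            PerfusateProfile(
                times=times,
                reservoir_concentrations=noisy,
                deposited_dose=deposited,
                reservoir_volume=spec.reservoir_volume,
                sample_volume=spec.sample_volume,
                device_residual=device_residual,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Ussing serosal accumulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UssingSimSpec:
    seed: int = 0
    n_replicates: int = 6
    cv: float = 0.05
    papp: float = 6.04e-6  # cm/s
    donor_c0: float = 50.0  # nmol/mL
    schedule: Sequence[float] = (30.0, 60.0, 90.0, 120.0, 150.0, 180.0)
    chamber_volume: float = 3.0
    sample_volume: float = 1.0
    exposed_area: float = 0.12
    qc_failure_rate: float = 0.0
    teer_mean: float = 83.0
    teer_sd: float = 21.0
    genotype: Genotype | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.qc_failure_rate <= 1:
            raise ValueError("qc_failure_rate must lie in [0, 1]")


def gen_ussing(spec: UssingSimSpec) -> list[UssingExperiment]:
    """Simulate linear serosal flux with replacement-sampling dilution.

    TEER readings are drawn so that a ``qc_failure_rate`` fraction of segments
    fail the integrity rules (low initial TEER), the rest passing both the
    80 Ohm*cm^2 floor and the 10% decline limit.
    """
    rng = np.random.default_rng(spec.seed)
    flux_per_min = spec.papp * spec.exposed_area * spec.donor_c0 * 60.0
    times = np.asarray(spec.schedule, dtype=float)
    out = []
    for _ in range(spec.n_replicates):
        mass = 0.0
        prev_t = 0.0
        concs = np.empty_like(times)
        for i, t in enumerate(times):
            mass += flux_per_min * (t - prev_t)
            prev_t = t
            concs[i] = mass / spec.chamber_volume
            mass *= (spec.chamber_volume - spec.sample_volume) / spec.chamber_volume
        noisy = concs * _noise_factors(rng, spec.cv, len(times))
        if rng.uniform() < spec.qc_failure_rate:
            teer0 = rng.uniform(40.0, 79.0)
            decline = rng.uniform(0.0, 0.09)
        else:
            teer0 = 80.0 + abs(rng.normal(spec.teer_mean - 80.0, spec.teer_sd))
            decline = rng.uniform(0.0, 0.09)
        out.append(
            UssingExperiment(
                times=times,
                serosal_concentrations=noisy,
                donor_c0=spec.donor_c0,
                chamber_volume=spec.chamber_volume,
                sample_volume=spec.sample_volume,
                exposed_area=spec.exposed_area,
                teer_initial=teer0,
                teer_final=teer0 * (1.0 - decline),
                genotype=spec.genotype,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ATPase Michaelis-Menten curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MMSimSpec:
    seed: int = 0
    n_replicates: int = 1
    cv: float = 0.05
    vmax: float = 10.0  # uM/min
    km: float = 30.0  # uM
    grid: Sequence[float] = (1.0, 3.0, 10.0, 30.0, 60.0, 100.0, 200.0, 300.0)
    duplicates: int = 2
    additive_sd: float = 0.0
    membrane: Membrane | None = None


def gen_mm_curves(spec: MMSimSpec) -> list[AtpaseCurve]:
    """Saturation curves ``v = Vmax*S/(Km+S)`` on the 0-300 uM design grid."""
    rng = np.random.default_rng(spec.seed)
    s = np.repeat(np.asarray(spec.grid, dtype=float), spec.duplicates)
    out = []
    for rep in range(spec.n_replicates):
        v = spec.vmax * s / (spec.km + s)
        v = v * _noise_factors(rng, spec.cv, len(s))
        if spec.additive_sd > 0:
            v = v + rng.normal(0.0, spec.additive_sd, size=len(s))
        out.append(
            AtpaseCurve(
                concentrations=s, rates=v, membrane=spec.membrane, replicate=rep
            )
        )
    return out


# ---------------------------------------------------------------------------
# Two-class descriptor matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptorClassSpec:
    """Two multivariate-normal compound classes separated along a polarity axis.

    The mean shift (``effect_size``, in unit-variance descriptor units along
    the polarity direction) defaults to the separation measured between the
    two groups of the packaged descriptor fixture.  A variance-dominant
    nuisance direction along bulk/size descriptors, orthogonalised against the
    polarity axis, exercises the orthogonal-component removal of OPLS-DA.
    """

    seed: int = 0
    n_a: int = 8
    n_b: int = 10
    effect_size: float = 3.2
    nuisance_sd: float = 3.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("need >= 2 compounds per class")
        if self.noise_sd <= 0:
            raise ValueError(
                "noise_sd must be positive (zero noise makes unloaded "
                "descriptor columns constant and unscalable)"
            )


def _polarity_nuisance_directions() -> tuple[np.ndarray, np.ndarray]:
    d_pol = np.array(
        [1.0 if n in POLARITY_DESCRIPTORS else 0.0 for n in CANONICAL_DESCRIPTORS]
    )
    d_pol /= np.linalg.norm(d_pol)
    d_nui = np.array(
        [1.0 if n in _SIZE_DESCRIPTORS else 0.0 for n in CANONICAL_DESCRIPTORS]
    )
    d_nui -= (d_nui @ d_pol) * d_pol
    d_nui /= np.linalg.norm(d_nui)
    return d_pol, d_nui


def gen_descriptor_classes(
    spec: DescriptorClassSpec,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Generate a labelled descriptor matrix plus its true discriminant.

    Returns ``(matrix, d)`` where ``d`` is the unit polarity direction (in
    unit-variance descriptor space) along which class A sits ``effect_size``
    above class B.  Count descriptors are rounded to non-negative integers and
    ``hb_total`` is rebuilt as ``hbd + hba`` so every record satisfies the
    bookkeeping invariants of :class:`CompoundRecord`.
    """
    rng = np.random.default_rng(spec.seed)
    d_pol, d_nui = _polarity_nuisance_directions()
    n = spec.n_a + spec.n_b
    labels = [Group.A] * spec.n_a + [Group.B] * spec.n_b
    shift = np.where(
        np.arange(n) < spec.n_a, spec.effect_size / 2.0, -spec.effect_size / 2.0
    )
    latent = (
        np.outer(shift, d_pol)
        + np.outer(rng.normal(0.0, spec.nuisance_sd, n), d_nui)
        + rng.normal(0.0, spec.noise_sd, (n, len(CANONICAL_DESCRIPTORS)))
    )
    raw = _RAW_MEAN + _RAW_SD * latent
    hbd_i = CANONICAL_DESCRIPTORS.index("hbd")
    hba_i = CANONICAL_DESCRIPTORS.index("hba")
    tot_i = CANONICAL_DESCRIPTORS.index("hb_total")
    for idx in _INTEGER_IDX:
        raw[:, idx] = np.clip(np.round(raw[:, idx]), 0, None)
    raw[:, tot_i] = raw[:, hbd_i] + raw[:, hba_i]
    records = tuple(
        CompoundRecord(
            name=f"sim{i:03d}",
            group=labels[i],
            descriptors=dict(zip(CANONICAL_DESCRIPTORS, raw[i])),
        )
        for i in range(n)
    )
    return DescriptorMatrix(records=records), d_pol
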