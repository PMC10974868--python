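"""Synthetic data generation for every pipeline stage.

Emulates the three experimental data streams so the analysis chain is fully
testable without measured data: noisy chamber dissolution profiles from known
coefficients, per-animal closed-loop perfusion series with zero-order water
reabsorption, and oral plasma profiles from known two-compartment parameters.

Noise is proportional log-normal by default (positive assay-like CV);
additive Gaussian noise is available.  Replicates draw from disjoint spawned
seed streams, so generation is bit-for-bit reproducible for a given seed and
replicate index.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .gis_model import simulate_gis
from .types import (
    DissolutionProfile,
    FormulationParams,
    GISConfig,
    PerfusionDataset,
    PKParams,
    PlasmaProfile,
)

__all__ = [
    "SynthSpec",
    "PerfusionTruth",
    "make_gis_profiles",
    "make_perfusion_data",
    "make_plasma_profiles",
    "oral_two_compartment_conc",
]


@dataclass
class PerfusionTruth:
    """Generating parameters for one perfusion experiment."""

    C0: float = 0.1        # initial luminal concentration (mg/mL)
    ka: float = 0.0123     # absorption rate constant (1/min)
    k0: float = 0.02       # zero-order water reabsorption (mL/min)
    V0: float = 10.4       # initial loop volume (mL)
    t_end: float = 30.0    # experiment duration (min)


@dataclass
class SynthSpec:
    """Specification of one synthetic dataset."""

    seed: int = 0
    noise_model: Literal["proportional", "additive"] = "proportional"
    noise_cv: float = 0.0
    n_replicates: int = 1
    sampling_times: Optional[np.ndarray] = None
    # exactly one of the generating-parameter blocks is used per generator
    formulation: Optional[FormulationParams] = None
    gis_config: Optional[GISConfig] = None
    perfusion: PerfusionTruth = field(default_factory=PerfusionTruth)
    pk: Optional[PKParams] = None
    dose: float = 320.0
    # first-order oral absorption for plasma profiles; default is the measured
    # absorption rate constant of the reference product (0.74 1/h)
    ka_oral: float = 0.74 / 60.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _noisy(values: np.ndarray, spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_cv == 0:
        return values.copy()
    if spec.noise_model == "proportional":
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        out = values * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)
    else:
        out = values + rng.normal(0.0, spec.noise_cv * np.maximum(values, 0.0), size=values.shape)
    return np.clip(out, 0.0, None)


def _streams(spec: SynthSpec) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)]


def make_gis_profiles(spec: SynthSpec) -> list[list[DissolutionProfile]]:
    """Noisy chamber dissolution profiles; one list of per-chamber profiles
    per replicate tablet."""
    if spec.formulation is None or spec.gis_config is None:
        raise ValueError("make_gis_profiles needs spec.formulation and spec.gis_config")
    times = spec.sampling_times
    if times is None:
        times = np.arange(0.0, spec.gis_config.t_end + 1e-9, 10.0)
    sim = simulate_gis(spec.gis_config, spec.formulation, times=times)
    replicates = []
    for rng in _streams(spec):
        profs = []
        for chamber, clean in sim.profiles.items():
            profs.append(DissolutionProfile(
                times=clean.times, chamber=chamber,
                amount_dissolved=_noisy(clean.amount_dissolved, spec, rng),
            ))
        replicates.append(profs)
    return replicates


def mean_profiles(replicates: list[list[DissolutionProfile]]) -> list[DissolutionProfile]:
    """Average replicate tablets chamber-wise (the default fitting input)."""
    by_chamber: dict[str, list[DissolutionProfile]] = {}
    for rep in replicates:
        for prof in rep:
            by_chamber.setdefault(prof.chamber, []).append(prof)
    out = []
    for chamber, profs in by_chamber.items():
        out.append(DissolutionProfile(
            times=profs[0].times, chamber=chamber,
            amount_dissolved=np.mean([p.amount_dissolved for p in profs], axis=0),
        ))
    return out


def make_perfusion_data(spec: SynthSpec) -> list[PerfusionDataset]:
    """Per-animal closed-loop perfusion datasets.

    The clean luminal decay is ``C0*exp(-ka*t)`` on the no-reabsorption
    scale; samples are back-transformed through the volume correction
    (divide by ``Vt/V0``) so that the analysis pipeline's forward correction
    is exercised, then measurement noise is applied.
    """
    p = spec.perfusion
    times = spec.sampling_times
    if times is None:
        times = np.arange(5.0, p.t_end + 1e-9, 5.0)
    vt = p.V0 - p.k0 * times
    if np.any(vt <= 0):
        raise ValueError("reabsorption exhausts the loop volume before t_end")
    ct = p.C0 * np.exp(-p.ka * times)
    ce_clean = ct * p.V0 / vt
    datasets = []
    for i, rng in enumerate(_streams(spec)):
        ce = _noisy(ce_clean, spec, rng)
        datasets.append(PerfusionDataset(
            times=times, measured_conc=ce,
            V0=p.V0, Vend=p.V0 - p.k0 * p.t_end, t_end=p.t_end,
            animal_id=f"rat{i + 1}",
        ))
    return datasets


def oral_two_compartment_conc(
    times: np.ndarray, dose: float, ka: float, pk: PKParams
) -> np.ndarray:
    """Closed-form central concentration for first-order oral absorption into
    a two-compartment model (triexponential; rate constants in 1/min)."""
    alpha, beta = pk.hybrid_constants()
    k21 = pk.k21_min
    v = pk.Vc_over_Fsys
    times = np.asarray(times, dtype=float)
    coef_a = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    coef_b = (k21 - beta) / ((ka - beta) * (alpha - beta))
    coef_k = (k21 - ka) / ((alpha - ka) * (beta - ka))
    conc = (ka * dose / v) * (
        coef_a * np.exp(-alpha * times)
        + coef_b * np.exp(-beta * times)
        + coef_k * np.exp(-ka * times)
    )
    # clamp roundoff at t=0 (exact value is zero)
    return np.maximum(conc, 0.0)


def make_plasma_profiles(spec: SynthSpec) -> list[PlasmaProfile]:
    """Noisy oral plasma profiles from the closed-form two-compartment model
    with first-order absorption, at bioequivalence-like sampling times."""
    if spec.pk is None:
        raise ValueError("make_plasma_profiles needs spec.pk")
    times = spec.sampling_times
    if times is None:
        times = np.array([0.0, 30, 60, 90, 120, 180, 240, 360, 480, 720,
                          1440, 2160, 2880])
    clean = oral_two_compartment_conc(times, spec.dose, spec.ka_oral, spec.pk)
    profiles = []
    for i, rng in enumerate(_streams(spec)):
        profiles.append(PlasmaProfile(
            times=times, conc=_noisy(clean, spec, rng), formulation=f"subject{i + 1}",
        ))
    return profiles
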