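"""Closed-loop (Doluisio-type) in-situ perfusion analysis.

The luminal drug concentration in a perfused intestinal loop decays
mono-exponentially with the absorption rate constant ``ka``.  Water is
reabsorbed from the loop as a zero-order process, so measured concentrations
are first corrected to the no-reabsorption scale:

* ``k0 = (V0 - Vend) / t_end`` — zero-order water reabsorption (mL/min),
  from the directly measured initial and final loop volumes.  (The printed
  source formula lacks parentheses; this difference-quotient reading is the
  dimensionally consistent one.)
* ``Ct = Ce * Vt / V0`` with ``Vt = V0 - k0*t`` — volume-corrected
  concentration.
* ``Ct = C0 * exp(-ka*t)`` — nonlinear least-squares fit for ``ka``.
* ``Peff = ka * R / 2`` — permeability of a cylindrical segment of radius
  ``R``.  (Adopted over the ambiguous ``ka x R2`` rendering of the same
  relation.)
* rat-to-human scaling by a fixed factor (default 4).
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .types import PerfusionDataset, PermeabilityResult

__all__ = [
    "estimate_k0",
    "correct_concentration",
    "fit_ka",
    "ka_to_peff",
    "scale_rat_to_human",
    "analyze_perfusion",
]

#: Effective radius of the perfused rat small intestine (cm).
R_RAT = 0.18
#: Average rat-to-human permeability conversion factor.
HUMAN_SCALE = 4.0


def estimate_k0(V0: float, Vend: float, t_end: float) -> float:
    """Zero-order water-reabsorption constant ``(V0 - Vend)/t_end`` (mL/min)."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if V0 < Vend:
        raise ValueError("V0 must be >= Vend")
    return (V0 - Vend) / t_end


def correct_concentration(
    Ce: float | np.ndarray, t: float | np.ndarray, k0: float, V0: float
) -> float | np.ndarray:
    """Volume-corrected luminal concentration ``Ce * (V0 - k0*t) / V0``."""
    Ce = np.asarray(Ce, dtype=float)
    t = np.asarray(t, dtype=float)
    Vt = V0 - k0 * t
    if np.any(Vt <= 0):
        raise ValueError("water reabsorption exhausted the loop volume (Vt <= 0)")
    out = Ce * Vt / V0
    return float(out) if out.ndim == 0 else out


def fit_ka(dataset: PerfusionDataset) -> tuple[float, float]:
    """Mono-exponential absorption fit on volume-corrected concentrations.

    Plain (untransformed) nonlinear least squares of ``C0 * exp(-ka*t)``,
    initialized from the log-linear regression estimate; returns
    ``(ka, C0_fit)`` in 1/min and mg/mL.
    """
    if dataset.times.size < 3:
        raise ValueError("need at least 3 sampling points to fit ka")
    k0 = estimate_k0(dataset.V0, dataset.Vend, dataset.t_end)
    ct = correct_concentration(dataset.measured_conc, dataset.times, k0, dataset.V0)
    if np.any(ct <= 0):
        raise ValueError("non-positive corrected concentration")
    # log-linear start values; slope clipped at zero for flat series
    if np.allclose(ct, ct[0]):
        return 0.0, float(ct[0])
    slope, intercept = np.polyfit(dataset.times, np.log(ct), 1)
    ka0 = max(-slope, 0.0)
    c00 = float(np.exp(intercept))
    popt, _ = curve_fit(
        lambda t, c0, ka: c0 * np.exp(-ka * t),
        dataset.times, ct, p0=[c00, max(ka0, 1e-6)], maxfev=10000,
    )
    c0_fit, ka = float(popt[0]), float(popt[1])
    return ka, c0_fit


def ka_to_peff(ka: float, R: float = R_RAT) -> float:
    """Effective permeability ``ka * R / 2`` (cm/min) for a cylindrical
    segment; ``ka`` in 1/min."""
    return ka * R / 2.0


def scale_rat_to_human(Peff_rat: float, factor: float = HUMAN_SCALE) -> float:
    """Scale a rat permeability to the human value by a fixed factor."""
    if Peff_rat < 0:
        raise ValueError("Peff_rat must be non-negative")
    return Peff_rat * factor


def analyze_perfusion(
    datasets: list[PerfusionDataset],
    *,
    R: float = R_RAT,
    scale_factor: float = HUMAN_SCALE,
    pooled: bool = False,
) -> PermeabilityResult:
    """Full pipeline over a group of animals: per-animal k0 and ka, averaged
    across animals (default), then conversion to permeability and scaling.

    With ``pooled=True`` the volume-corrected points of all animals are fit
    jointly instead of per animal.
    """
    if not datasets:
        raise ValueError("no perfusion datasets supplied")
    per_animal = []
    for ds in datasets:
        k0 = estimate_k0(ds.V0, ds.Vend, ds.t_end)
        ka, c0 = fit_ka(ds)
        per_animal.append({"animal_id": ds.animal_id, "k0": k0, "ka": ka, "C0_fit": c0})

    if pooled:
        t_all = np.concatenate([ds.times for ds in datasets])
        ct_all = np.concatenate([
            correct_concentration(ds.measured_conc, ds.times,
                                  estimate_k0(ds.V0, ds.Vend, ds.t_end), ds.V0)
            for ds in datasets
        ])
        order = np.argsort(t_all, kind="stable")
        slope, intercept = np.polyfit(t_all, np.log(ct_all), 1)
        popt, _ = curve_fit(
            lambda t, c0, ka: c0 * np.exp(-ka * t),
            t_all[order], ct_all[order],
            p0=[float(np.exp(intercept)), max(-slope, 1e-6)], maxfev=10000,
        )
        ka_mean, c0_mean = float(popt[1]), float(popt[0])
    else:
        ka_mean = float(np.mean([a["ka"] for a in per_animal]))
        c0_mean = float(np.mean([a["C0_fit"] for a in per_animal]))

    peff_rat = ka_to_peff(ka_mean, R)
    return PermeabilityResult(
        k0=float(np.mean([a["k0"] for a in per_animal])),
        ka=ka_mean,
        C0_fit=c0_mean,
        Peff_rat=peff_rat,
        Peff_human=scale_rat_to_human(peff_rat, scale_factor),
        scale_factor=scale_factor,
        per_animal=per_animal,
    )
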