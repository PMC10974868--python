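"""Non-compartmental analysis: Cmax/Tmax, AUC by the linear trapezoidal rule,
and signed prediction errors against observed exposure metrics."""
from __future__ import annotations

import numpy as np

from .types import NCAResult, PlasmaProfile

__all__ = ["cmax", "auc_trapezoid", "nca_metrics", "prediction_error"]


def cmax(profile: PlasmaProfile) -> tuple[float, float]:
    """Maximum concentration and the first time attaining it."""
    if profile.times.size == 0:
        raise ValueError("profile is empty")
    i = int(np.argmax(profile.conc))
    return float(profile.conc[i]), float(profile.times[i])


def auc_trapezoid(profile: PlasmaProfile, t_end: float | None = None) -> float:
    """Linear-trapezoidal AUC from the first sample up to ``t_end``.

    ``t_end`` must not exceed the last sampling time (no extrapolation); if it
    falls between samples, the final partial trapezoid is interpolated
    linearly, which is exact for piecewise-linear profiles.
    """
    t, c = profile.times, profile.conc
    if t.size == 0:
        raise ValueError("profile is empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-12:
        raise ValueError(f"t_end={t_end} beyond last sampling time {t[-1]}")
    if t_end <= t[0]:
        return 0.0
    inside = t <= t_end
    tt, cc = t[inside], c[inside]
    area = float(np.trapezoid(cc, tt))
    if tt[-1] < t_end:  # partial last trapezoid
        c_end = float(np.interp(t_end, t, c))
        area += 0.5 * (c_end + cc[-1]) * (t_end - tt[-1])
    return area


def nca_metrics(profile: PlasmaProfile, t_end: float | None = None) -> NCAResult:
    """Cmax/Tmax and AUC0-t for one profile."""
    cm, tm = cmax(profile)
    t_last = float(profile.times[-1]) if t_end is None else float(t_end)
    return NCAResult(Cmax=cm, Tmax=tm, AUC0t=auc_trapezoid(profile, t_end), t_last=t_last)


def prediction_error(experimental: float, predicted: float) -> float:
    """Signed prediction error ``100*(predicted - experimental)/experimental``
    (%); negative when the model under-predicts."""
    if experimental == 0:
        raise ValueError("experimental value must be non-zero")
    return 100.0 * (predicted - experimental) / experimental
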