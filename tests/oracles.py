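"""Independent oracles for the test-suite.

These re-derive expected values through routes independent of the package's
solver path: a fixed-step explicit-Euler integration of the same mass-balance
equations (coded separately, plain Python floats), the closed-form
biexponential bolus solution of the two-compartment model, and a log-linear
regression estimate of a mono-exponential decay constant.
"""
from __future__ import annotations

import math

import numpy as np


def euler_gis(cfg, form, *, dt: float = 0.001, sample_times=None,
              kabs: float = 0.0, kt: float = 0.0, tcut: float | None = None,
              pk=None, k_ge: float | None = None):
    """Explicit-Euler integration of the transfer-dissolution system.

    Returns ``(times, dict of state series)`` sampled at ``sample_times``.
    Independent re-implementation: scalar arithmetic, fixed step, no SciPy.
    """
    if sample_times is None:
        sample_times = np.arange(0.0, cfg.t_end + 1e-9, 10.0)
    sample_times = np.asarray(sample_times, dtype=float)
    t_end = float(sample_times[-1])
    kge = math.log(2.0) / cfg.t_half_G if k_ge is None else k_ge
    acid = cfg.gastric_acid
    if acid is not None:
        anchors = sorted(acid.solubility_ph_anchors.items())
        anchor_ph = [a[0] for a in anchors]
        anchor_logcs = [math.log10(a[1]) for a in anchors]

        def stomach_cs(n_mmol, v):
            ph = -math.log10(max(n_mmol, 1e-12) / max(v, 1e-9))
            if ph <= anchor_ph[0]:
                return 10.0 ** anchor_logcs[0]
            if ph >= anchor_ph[-1]:
                return 10.0 ** anchor_logcs[-1]
            for i in range(len(anchor_ph) - 1):
                if anchor_ph[i] <= ph <= anchor_ph[i + 1]:
                    frac = (ph - anchor_ph[i]) / (anchor_ph[i + 1] - anchor_ph[i])
                    return 10.0 ** (anchor_logcs[i] + frac * (anchor_logcs[i + 1] - anchor_logcs[i]))
    else:
        static_cs_s = cfg.solubility_by_compartment["stomach"]

        def stomach_cs(n_mmol, v):
            return static_cs_s
    cs_d = cfg.solubility_by_compartment["duodenum"]
    cs_j = cfg.solubility_by_compartment["jejunum"]
    zs, zd, zj, kpre = form.Zs, form.Zd, form.Zj, form.kpre_s
    vd = cfg.Vd
    suspend = cfg.solid_transits_duodenum

    if pk is not None:
        k10, k12, k21 = pk.k10_min, pk.k12_min, pk.k21_min
    else:
        k10 = k12 = k21 = 0.0

    # state
    as_s, ad_s, ap_s, vs = cfg.dose, 0.0, 0.0, cfg.Vs0
    n_acid = acid.initial_mmol if acid is not None else 0.0
    as_d = ad_d = ap_d = 0.0
    as_j = ad_j = ap_j = 0.0
    vj = cfg.Vj0
    as_x = ad_x = ap_x = 0.0
    ac = aper = ael = 0.0

    n_steps = int(round(t_end / dt))
    sample_idx = set(int(round(ts / dt)) for ts in sample_times)
    out: dict[str, list[float]] = {k: [] for k in (
        "dissolved_stomach", "dissolved_duodenum", "dissolved_jejunum",
        "solid_stomach", "solid_duodenum", "precip_stomach",
        "V_stomach", "V_jejunum", "central", "total_mass")}

    def record():
        out["dissolved_stomach"].append(ad_s)
        out["dissolved_duodenum"].append(ad_d)
        out["dissolved_jejunum"].append(ad_j)
        out["solid_stomach"].append(as_s)
        out["solid_duodenum"].append(as_d)
        out["precip_stomach"].append(ap_s)
        out["V_stomach"].append(vs)
        out["V_jejunum"].append(vj)
        out["central"].append(ac)
        out["total_mass"].append(
            as_s + ad_s + ap_s + as_d + ad_d + ap_d + as_j + ad_j + ap_j
            + as_x + ad_x + ap_x + ac + aper + ael)

    if 0 in sample_idx:
        record()
    for step in range(1, n_steps + 1):
        t = (step - 1) * dt
        ka = kabs if (tcut is None or t < tcut) else 0.0

        cs_s = stomach_cs(n_acid, vs)
        c_s = ad_s / vs if vs > 1e-9 else 0.0
        diss_s = zs * as_s * (cs_s - c_s) if (as_s > 0.0 and c_s < cs_s) else 0.0
        prec_s = kpre * (c_s - cs_s) * vs if c_s > cs_s else 0.0
        dvs = cfg.ksec_s - kge * vs
        if vs <= cfg.Vs_min and dvs < 0.0:
            dvs = 0.0
        dn = (acid.secretion_conc * cfg.ksec_s - kge * n_acid) if acid is not None else 0.0

        c_d = ad_d / vd
        diss_d = zd * as_d * (cs_d - c_d) if (as_d > 0.0 and c_d < cs_d) else 0.0
        q = kge * vs + cfg.ksec_d
        kflow = q / vd
        ksol = kflow if suspend else 0.0

        c_j = ad_j / vj if vj > 1e-6 else 0.0
        diss_j = zj * as_j * (cs_j - c_j) if (as_j > 0.0 and c_j < cs_j) else 0.0

        n_n_acid = n_acid + dt * dn
        n_as_s = as_s + dt * (-diss_s - kge * as_s)
        n_ad_s = ad_s + dt * (diss_s - prec_s - kge * ad_s)
        n_ap_s = ap_s + dt * (prec_s - kge * ap_s)
        n_vs = vs + dt * dvs
        n_as_d = as_d + dt * (kge * as_s - diss_d - ksol * as_d)
        n_ad_d = ad_d + dt * (kge * ad_s + diss_d - kflow * ad_d - ka * ad_d)
        n_ap_d = ap_d + dt * (kge * ap_s - kflow * ap_d)
        n_as_j = as_j + dt * (ksol * as_d - diss_j - kt * as_j)
        n_ad_j = ad_j + dt * (kflow * ad_d + diss_j - kt * ad_j - ka * ad_j)
        n_ap_j = ap_j + dt * (kflow * ap_d - kt * ap_j)
        n_vj = vj + dt * (q - kt * vj)
        n_as_x = as_x + dt * (kt * as_j)
        n_ad_x = ad_x + dt * (kt * ad_j - ka * ad_x)
        n_ap_x = ap_x + dt * (kt * ap_j)
        absorbed = ka * (ad_d + ad_j + ad_x)
        n_ac = ac + dt * (absorbed - (k10 + k12) * ac + k21 * aper)
        n_aper = aper + dt * (k12 * ac - k21 * aper)
        n_ael = ael + dt * (k10 * ac)

        (as_s, ad_s, ap_s, vs, n_acid, as_d, ad_d, ap_d, as_j, ad_j, ap_j, vj,
         as_x, ad_x, ap_x, ac, aper, ael) = (
            n_as_s, n_ad_s, n_ap_s, n_vs, n_n_acid, n_as_d, n_ad_d, n_ap_d,
            n_as_j, n_ad_j, n_ap_j, n_vj, n_as_x, n_ad_x, n_ap_x,
            n_ac, n_aper, n_ael)

        if step in sample_idx:
            record()

    return sample_times, {k: np.asarray(v) for k, v in out.items()}


def biexponential_bolus(pk, dose: float, times) -> np.ndarray:
    """Closed-form central concentration after an IV-type bolus into the
    central compartment of a two-compartment model (eigenvalue form)."""
    times = np.asarray(times, dtype=float)
    k10, k12, k21 = pk.k10_min, pk.k12_min, pk.k21_min
    s = k10 + k12 + k21
    disc = math.sqrt(s * s - 4.0 * k10 * k21)
    alpha, beta = (s + disc) / 2.0, (s - disc) / 2.0
    a = (alpha - k21) / (alpha - beta)
    b = (k21 - beta) / (alpha - beta)
    return (dose / pk.Vc_over_Fsys) * (a * np.exp(-alpha * times) + b * np.exp(-beta * times))


def loglinear_ka(times, conc) -> tuple[float, float]:
    """Closed-form log-linear regression estimate (ka, C0) of C0*exp(-ka*t)."""
    times = np.asarray(times, dtype=float)
    y = np.log(np.asarray(conc, dtype=float))
    slope, intercept = np.polyfit(times, y, 1)
    return -float(slope), float(np.exp(intercept))
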