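"""Mass-transport model of the three-chamber transfer-dissolution system.

The state tracks solid, dissolved and precipitated drug in the stomach,
duodenum and jejunum (plus, for the in-vivo variant driven by :mod:`.pbbm`,
a distal gut pool and the two disposition compartments), together with the
gastric and jejunal volumes:

* stomach — first-order emptying of all drug phases at ``k_ge = ln2/t_half_G``;
  z-factor dissolution against the gastric solubility; precipitation of
  supersaturated dissolved drug (the only chamber where precipitation acts);
  acid secretion inflow, so the volume relaxes from ``Vs0`` toward
  ``ksec_s/k_ge`` (floored at ``Vs_min``).
* duodenum — constant volume; receives the gastric output plus buffer
  secretion; the outflow pump balances the inflows.  Dissolved and
  precipitated drug leave with the liquid; undissolved particles are by
  default retained until dissolved (toggle ``solid_transits_duodenum``).
* jejunum — accumulative receiver of the duodenal outflow with its own
  (usually negligible) dissolution coefficient.

Dissolution follows the z-factor form ``Z * A_solid * (Cs - C)``, clamped at
saturation; precipitation is ``kpre * (C - Cs) * V`` above saturation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .types import CHAMBERS, DissolutionProfile, FormulationParams, GISConfig, PKParams

__all__ = [
    "STATE_NAMES",
    "GISSimulation",
    "SolverError",
    "gastric_volume",
    "dissolution_rate",
    "precipitation_rate",
    "simulate_gis",
]

#: Order of the integrated state vector (``acid_stomach`` is mmol of free
#: acid, all other non-volume states are drug mass in mg).
STATE_NAMES: tuple[str, ...] = (
    "solid_stomach", "dissolved_stomach", "precip_stomach", "V_stomach",
    "acid_stomach",
    "solid_duodenum", "dissolved_duodenum", "precip_duodenum",
    "solid_jejunum", "dissolved_jejunum", "precip_jejunum", "V_jejunum",
    "solid_distal", "dissolved_distal", "precip_distal",
    "central", "peripheral", "eliminated",
)
_IX = {name: i for i, name in enumerate(STATE_NAMES)}
#: Indices of drug-mass states (excludes the volumes and the acid amount).
MASS_STATES = tuple(
    i for i, n in enumerate(STATE_NAMES) if not (n.startswith("V_") or n.startswith("acid"))
)

_RTOL = 1e-8
_ATOL = 1e-10


class SolverError(RuntimeError):
    """Raised when the ODE integration fails or produces non-finite states."""


def gastric_volume(t: float | np.ndarray, cfg: GISConfig) -> float | np.ndarray:
    """Gastric volume at time ``t`` (min).

    Solves ``dVs/dt = ksec_s - k_ge*Vs`` from ``Vs(0) = Vs0`` and floors the
    result at ``Vs_min``:  ``Vs(t) = Vss + (Vs0 - Vss) exp(-k_ge t)`` with the
    steady state ``Vss = ksec_s/k_ge``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if cfg.t_half_G <= 0:  # pragma: no cover - pydantic already enforces this
        raise ValueError("t_half_G must be positive")
    vss = cfg.ksec_s / cfg.k_ge
    v = vss + (cfg.Vs0 - vss) * np.exp(-cfg.k_ge * t)
    v = np.maximum(v, cfg.Vs_min)
    return float(v) if v.ndim == 0 else v


def dissolution_rate(A_solid: float, C: float, Cs: float, Z: float) -> float:
    """z-factor dissolution rate ``Z * A_solid * (Cs - C)`` (mg/min).

    Zero when no solid remains or the solution is at/above saturation;
    dissolution is never negative (supersaturation is relieved only by
    precipitation, where enabled).
    """
    if A_solid <= 0.0 or C >= Cs:
        return 0.0
    return Z * A_solid * (Cs - C)


def precipitation_rate(C: float, Cs: float, V: float, kpre: float) -> float:
    """Precipitation rate ``kpre * (C - Cs) * V`` (mg/min) above saturation, else 0."""
    if C <= Cs:
        return 0.0
    return kpre * (C - Cs) * V


def gastric_solubility(acid_mmol: float, Vs: float, cfg: GISConfig) -> float:
    """Stomach saturation solubility (mg/mL) — static map entry, or the
    pH-interpolated value when the gastric acidity state is enabled."""
    acid = cfg.gastric_acid
    if acid is None:
        return cfg.solubility_by_compartment["stomach"]
    conc = max(acid_mmol, 1e-12) / max(Vs, 1e-9)  # mmol/mL == mol/L
    ph = -math.log10(conc)
    anchors = sorted(acid.solubility_ph_anchors.items())
    phs = [a[0] for a in anchors]
    logcs = [math.log10(a[1]) for a in anchors]
    return 10.0 ** float(np.interp(ph, phs, logcs))


def _rhs(
    t: float,
    y: np.ndarray,
    cfg: GISConfig,
    form: FormulationParams,
    k_ge: float,
    kabs: float,
    kt: float,
    pk: PKParams | None,
) -> np.ndarray:
    (As_s, Ad_s, Ap_s, Vs, Nacid, As_d, Ad_d, Ap_d,
     As_j, Ad_j, Ap_j, Vj, As_x, Ad_x, Ap_x, Ac, Aper, _Ael) = y

    cs_s = gastric_solubility(Nacid, Vs, cfg)
    cs_d = cfg.solubility_by_compartment["duodenum"]
    cs_j = cfg.solubility_by_compartment["jejunum"]

    Vs_eff = max(Vs, 1e-9)
    C_s = Ad_s / Vs_eff
    diss_s = dissolution_rate(As_s, C_s, cs_s, form.Zs)
    prec_s = precipitation_rate(C_s, cs_s, Vs_eff, form.kpre_s)

    dVs = cfg.ksec_s - k_ge * Vs
    if Vs <= cfg.Vs_min and dVs < 0.0:
        dVs = 0.0
    # acid turnover: secreted in with SGF, emptied first-order with the contents
    if cfg.gastric_acid is not None:
        dN = cfg.gastric_acid.secretion_conc * cfg.ksec_s - k_ge * Nacid
    else:
        dN = 0.0

    C_d = Ad_d / cfg.Vd
    diss_d = dissolution_rate(As_d, C_d, cs_d, form.Zd)
    # liquid outflow balances gastric output + duodenal secretion
    Q = k_ge * Vs + cfg.ksec_d
    kflow = Q / cfg.Vd
    ksol = kflow if cfg.solid_transits_duodenum else 0.0
    kpre_back = kflow if cfg.precipitate_redissolves else 0.0

    C_j = Ad_j / max(Vj, 1e-6)
    diss_j = dissolution_rate(As_j, C_j, cs_j, form.Zj)

    dAs_s = -diss_s - k_ge * As_s
    dAd_s = diss_s - prec_s - k_ge * Ad_s
    dAp_s = prec_s - k_ge * Ap_s

    # precipitate arriving from the stomach optionally rejoins the solid pool
    dAs_d = k_ge * As_s - diss_d - ksol * As_d + kpre_back * Ap_d
    dAd_d = k_ge * Ad_s + diss_d - kflow * Ad_d - kabs * Ad_d
    dAp_d = k_ge * Ap_s - kflow * Ap_d - kpre_back * Ap_d

    dAs_j = ksol * As_d - diss_j - kt * As_j
    dAd_j = kflow * Ad_d + diss_j - kt * Ad_j - kabs * Ad_j
    dAp_j = kflow * Ap_d - kt * Ap_j
    dVj = Q - kt * Vj

    dAs_x = kt * As_j
    dAd_x = kt * Ad_j - kabs * Ad_x
    dAp_x = kt * Ap_j

    absorbed = kabs * (Ad_d + Ad_j + Ad_x)
    if pk is not None:
        dAc = absorbed - (pk.k10_min + pk.k12_min) * Ac + pk.k21_min * Aper
        dAper = pk.k12_min * Ac - pk.k21_min * Aper
        dAel = pk.k10_min * Ac
    else:
        dAc = dAper = dAel = 0.0

    return np.array([
        dAs_s, dAd_s, dAp_s, dVs, dN, dAs_d, dAd_d, dAp_d,
        dAs_j, dAd_j, dAp_j, dVj, dAs_x, dAd_x, dAp_x, dAc, dAper, dAel,
    ])


def _integrate(
    cfg: GISConfig,
    form: FormulationParams,
    times: np.ndarray,
    *,
    k_ge: float | None = None,
    kabs: float = 0.0,
    kt: float = 0.0,
    tcut: float | None = None,
    pk: PKParams | None = None,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> pd.DataFrame:
    """Integrate the full system on ``times``; absorption is switched off at
    ``tcut`` by splitting the integration there."""
    k_ge = cfg.k_ge if k_ge is None else k_ge
    y0 = np.zeros(len(STATE_NAMES))
    y0[_IX["solid_stomach"]] = cfg.dose
    y0[_IX["V_stomach"]] = cfg.Vs0
    y0[_IX["V_jejunum"]] = cfg.Vj0
    if cfg.gastric_acid is not None:
        y0[_IX["acid_stomach"]] = cfg.gastric_acid.initial_mmol

    times = np.asarray(times, dtype=float)
    t_end = float(times[-1])
    if tcut is None or tcut >= t_end:
        legs = [(0.0, t_end, kabs)]
    else:
        legs = [(0.0, float(tcut), kabs), (float(tcut), t_end, 0.0)]

    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    y_start = y0
    t_collected = -np.inf
    for t0, t1, leg_kabs in legs:
        mask = (times >= t0) & (times <= t1)
        t_eval = np.union1d(times[mask], [t0, t1])
        sol = solve_ivp(
            _rhs, (t0, t1), y_start, t_eval=t_eval, method="LSODA",
            args=(cfg, form, k_ge, leg_kabs, kt, pk), rtol=rtol, atol=atol,
        )
        if not sol.success:
            _raise_diagnostic(sol)
        y_start = sol.y[:, -1]
        # keep requested output points only, without duplicating the split time
        keep = np.isin(sol.t, times) & (sol.t > t_collected)
        out_t.append(sol.t[keep])
        out_y.append(sol.y[:, keep])
        if sol.t[keep].size:
            t_collected = sol.t[keep][-1]

    t = np.concatenate(out_t)
    y = np.concatenate(out_y, axis=1)
    if not np.all(np.isfinite(y)):
        bad = next(STATE_NAMES[i] for i in range(y.shape[0]) if not np.all(np.isfinite(y[i])))
        raise SolverError(f"state variable {bad!r} became non-finite during integration")
    return pd.DataFrame(y.T, index=pd.Index(t, name="time_min"), columns=list(STATE_NAMES))


def _raise_diagnostic(sol) -> None:
    y_last = sol.y[:, -1] if sol.y.size else np.full(len(STATE_NAMES), np.nan)
    for name, val in zip(STATE_NAMES, y_last):
        if not np.isfinite(val):
            raise SolverError(f"integration failed; first non-finite state: {name!r}")
    raise SolverError(f"integration failed: {sol.message}")


@dataclass
class GISSimulation:
    """Trajectory of one simulator run plus per-chamber dissolution profiles."""

    config: GISConfig
    formulation: FormulationParams
    trajectory: pd.DataFrame

    @property
    def times(self) -> np.ndarray:
        return self.trajectory.index.to_numpy()

    def profile(self, chamber: str) -> DissolutionProfile:
        if chamber not in CHAMBERS:
            raise KeyError(f"unknown chamber {chamber!r}")
        return DissolutionProfile(
            times=self.times,
            chamber=chamber,
            amount_dissolved=self.trajectory[f"dissolved_{chamber}"].to_numpy(),
        )

    @property
    def profiles(self) -> dict[str, DissolutionProfile]:
        return {c: self.profile(c) for c in CHAMBERS}

    def chamber_volume(self, chamber: str) -> np.ndarray:
        if chamber == "stomach":
            return self.trajectory["V_stomach"].to_numpy()
        if chamber == "duodenum":
            return np.full(len(self.trajectory), self.config.Vd)
        if chamber == "jejunum":
            return self.trajectory["V_jejunum"].to_numpy()
        raise KeyError(f"unknown chamber {chamber!r}")

    def tidy(self) -> pd.DataFrame:
        """Long-format table: time_min, chamber, amount_dissolved_mg, volume_mL,
        concentration_mg_mL."""
        rows = []
        for chamber in CHAMBERS:
            amount = self.trajectory[f"dissolved_{chamber}"].to_numpy()
            volume = self.chamber_volume(chamber)
            with np.errstate(divide="ignore", invalid="ignore"):
                conc = np.where(volume > 0, amount / np.maximum(volume, 1e-12), 0.0)
            rows.append(pd.DataFrame({
                "time_min": self.times,
                "chamber": chamber,
                "amount_dissolved_mg": amount,
                "volume_mL": volume,
                "concentration_mg_mL": conc,
            }))
        return pd.concat(rows, ignore_index=True)

    def total_mass(self) -> np.ndarray:
        """Total drug accounted for at each output time (mg): gut phases plus,
        in vivo, the central/peripheral/eliminated amounts."""
        return self.trajectory.iloc[:, list(MASS_STATES)].sum(axis=1).to_numpy()

    def mass_balance_error(self) -> float:
        """Maximum relative deviation of the drug audit from the dose."""
        return float(np.max(np.abs(self.total_mass() - self.config.dose)) / self.config.dose)


def simulate_gis(
    cfg: GISConfig,
    form: FormulationParams,
    times: np.ndarray | None = None,
    *,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> GISSimulation:
    """Simulate the in-vitro transfer-dissolution run for one formulation.

    Returns per-chamber dissolved-amount profiles on the requested grid
    (default: the config's grid).  The drug audit over all phases and
    chambers stays within solver tolerance of the dose at every time.
    """
    if times is None:
        times = cfg.times()
    traj = _integrate(cfg, form, np.asarray(times, dtype=float), rtol=rtol, atol=atol)
    return GISSimulation(config=cfg, formulation=form, trajectory=traj)
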