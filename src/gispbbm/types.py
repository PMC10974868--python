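"""Domain types for the GIS transfer-dissolution model and the PBBM chain.

Units are minutes, millilitres and milligrams throughout the package; the
scenario loader converts per-hour rate constants at the boundary.  Disposition
constants are stored as printed (per hour) and exposed per minute through
properties, so fixture files stay verbatim copies of their sources.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import ClassVar, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

Compartment = Literal["stomach", "duodenum", "jejunum"]

#: Chambers of the three-vessel simulator, in transit order.
CHAMBERS: tuple[str, ...] = ("stomach", "duodenum", "jejunum")


class GastricAcidConfig(BaseModel):
    """Optional gastric acidity state driving a pH-dependent gastric solubility.

    The dosing medium is acid diluted with water (e.g. 50 mL of 0.01 M
    simulated gastric fluid plus 250 mL of water), while the secretion is
    undiluted SGF, so the gastric pH relaxes from its diluted starting value
    back to the secretion pH as the contents turn over.  The free-acid amount
    is a well-mixed state: inflow ``secretion_conc * ksec_s``, first-order
    outflow with gastric emptying.  Gastric solubility of the weak acid is
    interpolated log-linearly through measured (pH, Cs) anchors, clamped at
    the extreme anchors.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    secretion_conc: float = Field(gt=0, default=0.01, description="secreted acid (mmol/mL)")
    initial_mmol: float = Field(ge=0, default=0.5, description="acid in the dosed medium (mmol)")
    solubility_ph_anchors: dict[float, float] = Field(
        default={2.0: 0.08, 4.5: 1.23, 6.8: 9.21},
        description="pH -> saturation solubility (mg/mL) anchors",
    )

    @model_validator(mode="after")
    def _check(self) -> "GastricAcidConfig":
        if len(self.solubility_ph_anchors) < 2:
            raise ValueError("need at least two (pH, Cs) anchors")
        if any(cs <= 0 for cs in self.solubility_ph_anchors.values()):
            raise ValueError("solubility anchors must be positive")
        return self


class GISConfig(BaseModel):
    """Configuration of one gastrointestinal-simulator scenario.

    The device is a three-vessel transfer system: a gastric chamber that
    empties first-order into a constant-volume duodenal chamber, which
    overflows into an accumulative jejunal receiver.  Both the gastric and
    duodenal vessels receive secretion fluid at fixed volumetric rates.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    dose: float = Field(gt=0, description="drug dose placed in the stomach (mg)")
    ksec_s: float = Field(gt=0, description="gastric secretion rate (mL/min)")
    ksec_d: float = Field(gt=0, description="duodenal secretion rate (mL/min)")
    t_half_G: float = Field(gt=0, description="gastric emptying half-life (min)")
    Vs0: float = Field(gt=0, description="initial gastric volume (mL)")
    Vs_min: float = Field(gt=0, description="floor on the gastric volume (mL)")
    Vd: float = Field(gt=0, description="constant duodenal volume (mL)")
    Vj0: float = Field(ge=0, default=0.0, description="initial jejunal volume (mL)")
    solubility_by_compartment: dict[str, float] = Field(
        description="saturation solubility Cs per chamber (mg/mL)"
    )
    t_end: float = Field(gt=0, default=240.0, description="simulation end time (min)")
    n_grid: int = Field(gt=1, default=241, description="number of output time points")
    solid_transits_duodenum: bool = Field(
        default=False,
        description=(
            "if True, undissolved particles leave the duodenum in suspension at "
            "the liquid flow rate; by default solid is retained until dissolved"
        ),
    )
    precipitate_redissolves: bool = Field(
        default=False,
        description="if True, the precipitated pool re-enters the solid pool downstream",
    )
    gastric_acid: Optional[GastricAcidConfig] = Field(
        default=None,
        description=(
            "optional gastric acidity state; when set, the stomach solubility "
            "follows the pH trajectory instead of the static map entry"
        ),
    )

    @model_validator(mode="after")
    def _check(self) -> "GISConfig":
        if self.Vs_min >= self.Vs0:
            raise ValueError("Vs_min must be smaller than Vs0")
        missing = set(CHAMBERS) - set(self.solubility_by_compartment)
        if missing:
            raise ValueError(f"solubility map missing chambers: {sorted(missing)}")
        if any(v <= 0 for v in self.solubility_by_compartment.values()):
            raise ValueError("solubilities must be positive")
        return self

    @property
    def k_ge(self) -> float:
        """First-order gastric emptying constant ln2/t_half_G (1/min)."""
        return math.log(2.0) / self.t_half_G

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_grid)


class FormulationParams(BaseModel):
    """Per-product dissolution/precipitation coefficients and, for the in-vivo
    variant, the absorption parameters.

    ``Zs/Zd/Zj`` are z-factor dissolution coefficients (mL/mg/min) for the
    stomach, duodenum and jejunum; ``kpre_s`` is the stomach-only
    precipitation rate constant (1/min).  The in-vivo block carries the
    effective permeability, formulation-specific gastric half-life, the
    absorption-window cutoff ``tcut``, intestinal radius and the
    jejunum-to-distal transit constant.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str = "formulation"
    Zs: float = Field(ge=0)
    Zd: float = Field(ge=0)
    Zj: float = Field(ge=0)
    kpre_s: float = Field(ge=0)
    # in-vivo only
    Peff: Optional[float] = Field(default=None, ge=0, description="effective permeability (cm/min)")
    t_half_G: Optional[float] = Field(default=None, gt=0, description="in-vivo gastric half-life (min)")
    tcut: Optional[float] = Field(default=None, gt=0, description="absorption-window cutoff (min)")
    R: Optional[float] = Field(default=None, gt=0, description="intestinal radius (cm)")
    kt: Optional[float] = Field(default=None, ge=0, description="jejunum-to-distal transit constant (1/min)")

    IN_VIVO_FIELDS: ClassVar[tuple[str, ...]] = ("Peff", "t_half_G", "tcut", "R", "kt")

    def require_in_vivo(self) -> None:
        """Raise with the offending field name if an absorption parameter is unset."""
        for name in self.IN_VIVO_FIELDS:
            if getattr(self, name) is None:
                raise ValueError(
                    f"in-vivo simulation requires formulation field {name!r} "
                    f"(formulation {self.name!r})"
                )


class PKParams(BaseModel):
    """Two-compartment disposition constants (stored per hour, as reported)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    Vc_over_Fsys: float = Field(gt=0, description="apparent central volume Vc/Fsys (mL)")
    k10: float = Field(gt=0, description="elimination rate constant (1/h)")
    k12: float = Field(gt=0, description="central-to-peripheral rate constant (1/h)")
    k21: float = Field(gt=0, description="peripheral-to-central rate constant (1/h)")
    Fsys: float = Field(gt=0, le=1.0, default=1.0, description="systemic availability")

    @property
    def k10_min(self) -> float:
        return self.k10 / 60.0

    @property
    def k12_min(self) -> float:
        return self.k12 / 60.0

    @property
    def k21_min(self) -> float:
        return self.k21 / 60.0

    def hybrid_constants(self) -> tuple[float, float]:
        """Macro (alpha, beta) eigenvalue pair of the disposition system (1/min)."""
        s = self.k10_min + self.k12_min + self.k21_min
        p = self.k10_min * self.k21_min
        disc = math.sqrt(s * s - 4.0 * p)
        return (s + disc) / 2.0, (s - disc) / 2.0


class InVivoScaling(BaseModel):
    """Multipliers converting in-vitro dissolution/precipitation coefficients
    to their in-vivo counterparts."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    f_Zs: float = Field(gt=0, default=4.0)
    f_Zd: float = Field(gt=0, default=4.0)
    f_Zj: float = Field(gt=0, default=10.0)
    f_kpre: float = Field(gt=0, default=0.2)


@dataclass
class DissolutionProfile:
    """Dissolved-amount time series for one chamber.

    The jejunal chamber is an accumulative receiver, so its series is
    cumulative (non-decreasing).
    """

    times: np.ndarray
    chamber: str
    amount_dissolved: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amount_dissolved = np.asarray(self.amount_dissolved, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.amount_dissolved.shape:
            raise ValueError("times and amount_dissolved must be 1-D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PlasmaProfile:
    """Central-compartment concentration time series for one formulation."""

    times: np.ndarray
    conc: np.ndarray
    formulation: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have the same shape")


@dataclass
class PerfusionDataset:
    """One animal's closed-loop perfusion record.

    ``measured_conc`` are the raw luminal samples (mg/mL) before the
    water-reabsorption volume correction.
    """

    times: np.ndarray
    measured_conc: np.ndarray
    V0: float
    Vend: float
    t_end: float
    R_rat: float = 0.18
    L: float = 100.0
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.measured_conc = np.asarray(self.measured_conc, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.V0 >= self.Vend > 0):
            raise ValueError("require V0 >= Vend > 0")
        if np.any(self.measured_conc <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class Scenario:
    """A loaded scenario file: simulator config + formulation (+ disposition)."""

    name: str
    mode: Literal["in_vitro", "in_vivo"]
    gis: GISConfig
    formulation: FormulationParams
    pk: Optional[PKParams] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.mode == "in_vivo":
            if self.pk is None:
                raise ValueError(f"scenario {self.name!r}: in_vivo mode requires a pk block")
            self.formulation.require_in_vivo()


@dataclass
class NCAResult:
    """Non-compartmental summary of a plasma profile."""

    Cmax: float
    Tmax: float
    AUC0t: float
    t_last: float


@dataclass
class PermeabilityResult:
    """Output of the closed-loop perfusion analysis for one group of animals."""

    k0: float
    ka: float
    C0_fit: float
    Peff_rat: float
    Peff_human: float
    scale_factor: float
    per_animal: list[dict] = field(default_factory=list)


@dataclass
class FitResult:
    """Result of fitting dissolution/precipitation coefficients to profiles."""

    parameters: FormulationParams
    objective_value: float
    n_iterations: int
    converged: bool
    residuals_by_chamber: dict[str, float] = field(default_factory=dict)
    restarts: list[dict] = field(default_factory=list)
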