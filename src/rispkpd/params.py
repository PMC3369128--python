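"""Parameter containers for the risperidone/paliperidone PBPK-PD model.

The model couples a conventional two-compartment plasma PK model for
risperidone (RIS) and its active metabolite paliperidone (PALI) with a
physiologically parameterized brain: a vascular compartment perfused at
cerebral blood flow, an extra-vascular compartment exchanging with it by
passive diffusion and active (P-gp-like) efflux across the blood-brain
barrier, and free striatum / frontal-cortex compartments in which both drugs
compete for D2 and 5-HT2A receptors with explicit kon/koff kinetics.

Defaults are the published population estimates for the rat; all units are
per kg body weight (doses mg/kg, volumes L/kg, clearances L/h/kg) because the
source datasets carried no body weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

__all__ = [
    "PhysiologicalConstants",
    "PlasmaParameters",
    "BrainParameters",
    "ErrorModel",
    "IIVModel",
    "ModelParameters",
    "default_parameters",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class PhysiologicalConstants:
    """Fixed rat physiological constants and drug-specific unbound fractions.

    Volumes in L/kg, clearances in L/h/kg, molecular weights in g/mol.
    ``V_ev_total`` is the total extra-vascular brain water; the residual
    extra-vascular volume actually used in the mass balance is
    ``V_ev = V_ev_total - V_st - V_cx`` so that region volumes are disjoint.
    ``CL_exch`` is the fast extravascular<->region exchange clearance, fixed
    high so free striatum/cortex equilibrate rapidly with the rest of brain.
    """

    V_bv: float = 0.00024
    V_ev_total: float = 0.00656
    V_st: float = 0.0002
    V_cx: float = 0.0035
    CL_bv: float = 0.312   # cerebral blood flow
    CL_exch: float = 500.0
    fu_plasma_R: float = 0.0798
    fu_brain_R: float = 0.0699
    fu_plasma_P: float = 0.129
    fu_brain_P: float = 0.0755
    MW_R: float = 410.5
    MW_P: float = 426.5

    @property
    def V_ev(self) -> float:
        """Residual extra-vascular volume (L/kg), disjoint from regions."""
        return self.V_ev_total - self.V_st - self.V_cx

    def validate(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")
        for name in ("fu_plasma_R", "fu_brain_R", "fu_plasma_P", "fu_brain_P"):
            _require(getattr(self, name) <= 1.0, f"{name} must be in (0, 1]")
        _require(self.V_ev > 0, "V_ev_total must exceed V_st + V_cx")


@dataclass(frozen=True)
class PlasmaParameters:
    """Two-compartment plasma PK parameters for RIS and PALI.

    RIS elimination clearance is split into metabolic conversion to PALI
    (``CL_met``, mole-for-mole) and clearance by other routes (``CL_R``).
    IP dosing is an instantaneous central bolus with bioavailability ``F_IP``
    of which a fraction ``Fr_FPM`` is converted to PALI pre-systemically
    (first-pass metabolism). SC absorption is a zero-order filling of a depot
    over duration ``DR_SC`` with concurrent first-order drain ``Ka_SC``.
    """

    F_IP: float = 0.412
    F_SC: float = 0.816
    Fr_FPM: float = 0.268
    Ka_SC_R: float = 2.84
    Ka_SC_P: float = 1.31
    DR_SC_R: float = 0.161
    DR_SC_P: float = 0.162
    V_c_R: float = 1.29
    CL_R: float = 1.62
    CL_met: float = 0.775
    V_p_R: float = 0.169
    Q_R: float = 0.0882
    V_c_P: float = 1.27
    CL_P: float = 1.06
    V_p_P: float = 0.251
    Q_P: float = 0.269

    def validate(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")
        for name in ("F_IP", "F_SC", "Fr_FPM"):
            _require(getattr(self, name) <= 1.0, f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class BrainParameters:
    """Brain distribution and receptor-binding parameters.

    Passive BBB clearance ``CL_bev`` is shared by RIS and PALI; active efflux
    clearances are drug-specific. Binding constants (Kd in nM, koff in 1/h,
    Bmax in nM) are shared by the two drugs but receptor-specific; the
    association rate constant is always derived as kon = koff / Kd and never
    an independent parameter.
    """

    CL_bev: float = 2.13
    CL_eff_R: float = 9.97
    CL_eff_P: float = 47.0
    Kd_D2: float = 0.463
    koff_D2: float = 0.671
    Bmax_D2: float = 245.0
    Kd_5HT2A: float = 0.219
    koff_5HT2A: float = 0.525
    Bmax_5HT2A: float = 46.5

    @property
    def kon_D2(self) -> float:
        return self.koff_D2 / self.Kd_D2

    @property
    def kon_5HT2A(self) -> float:
        return self.koff_5HT2A / self.Kd_5HT2A

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            # Bmax = 0 is a legitimate degenerate setting (receptor knocked
            # out of the model, e.g. the D2-only scenario); rates must be > 0.
            if f.name.startswith("Bmax") or f.name.startswith("CL_eff"):
                _require(v >= 0, f"{f.name} must be >= 0")
            else:
                _require(v > 0, f"{f.name} must be > 0")


@dataclass(frozen=True)
class ErrorModel:
    """Residual error magnitudes.

    Concentrations carry proportional error expressed as the SD of the
    log-scale residual (exact log-normal form); receptor occupancies carry
    additive Gaussian error in percentage points.
    """

    sigma_prop_plasma_R: float = 0.233
    sigma_prop_plasma_P: float = 0.186
    sigma_prop_brain_R: float = 0.362
    sigma_prop_brain_P: float = 0.424
    sigma_add_RO_D2: float = 17.7
    sigma_add_RO_5HT2A: float = 18.2

    def validate(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")


#: plasma parameters that may carry inter-individual variability
IIV_PARAMETERS = ("F_IP", "Ka_SC_R", "Ka_SC_P", "DR_SC_R", "CL_R", "CL_P")

_DEFAULT_IIV = {
    "F_IP": 80.6,
    "Ka_SC_R": 46.4,
    "Ka_SC_P": 34.4,
    "DR_SC_R": 91.2,
    "CL_R": 30.5,
    "CL_P": 16.2,
}


@dataclass(frozen=True)
class IIVModel:
    """Log-normal inter-individual variability as %CV per plasma parameter.

    A parameter p with CV c (%) is sampled per animal as p * exp(eta) with
    eta ~ N(0, omega^2), omega^2 = ln(1 + (c/100)^2). Parameters not listed
    (all brain parameters in particular) have zero variability.
    """

    cv_percent: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_IIV)
    )

    def omega(self, name: str) -> float:
        """Log-scale SD for parameter ``name`` (0 if no IIV)."""
        c = self.cv_percent.get(name, 0.0) / 100.0
        return math.sqrt(math.log1p(c * c))

    def validate(self) -> None:
        for name, cv in self.cv_percent.items():
            _require(name in IIV_PARAMETERS,
                     f"IIV not supported on parameter {name!r}")
            _require(cv >= 0, f"IIV CV for {name} must be >= 0")

    def without_variability(self) -> "IIVModel":
        return IIVModel(cv_percent={})


@dataclass(frozen=True)
class ModelParameters:
    """Aggregate of every constant the model needs."""

    physiological: PhysiologicalConstants = field(
        default_factory=PhysiologicalConstants)
    plasma: PlasmaParameters = field(default_factory=PlasmaParameters)
    brain: BrainParameters = field(default_factory=BrainParameters)
    error: ErrorModel = field(default_factory=ErrorModel)
    iiv: IIVModel = field(default_factory=IIVModel)

    def validate(self) -> "ModelParameters":
        self.physiological.validate()
        self.plasma.validate()
        self.brain.validate()
        self.error.validate()
        self.iiv.validate()
        return self

    # convenience updaters (dataclasses are frozen) -------------------------

    def with_plasma(self, **kw) -> "ModelParameters":
        return replace(self, plasma=replace(self.plasma, **kw))

    def with_brain(self, **kw) -> "ModelParameters":
        return replace(self, brain=replace(self.brain, **kw))

    def with_physiological(self, **kw) -> "ModelParameters":
        return replace(self, physiological=replace(self.physiological, **kw))

    def with_error(self, **kw) -> "ModelParameters":
        return replace(self, error=replace(self.error, **kw))

    def mw(self, drug: str) -> float:
        if drug == "RIS":
            return self.physiological.MW_R
        if drug == "PALI":
            return self.physiological.MW_P
        raise ValueError(f"unknown drug {drug!r}")


def default_parameters() -> ModelParameters:
    """Published rat population estimates with fixed physiological constants."""
    return ModelParameters().validate()
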