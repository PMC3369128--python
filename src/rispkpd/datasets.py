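"""Synthetic destructive-sampling rat datasets.

The original plasma / brain / receptor-occupancy data behind the model are
proprietary; this module generates datasets with the same statistical
structure so that fitting and evaluation are reproducible: 12 study designs
(drug, route, dose ladder, sampling times, observation panel, rat count),
one animal per time point (animals are euthanized for brain measurements),
log-normal inter-individual variability on six plasma parameters,
exact log-normal proportional residual error on concentrations, additive
error in percentage points on occupancies, and optional below-LOQ flagging.

Observation tables are long-format pandas DataFrames with columns
``STUDY, ID, DRUG_ADMIN, ROUTE, DOSE, TIME, TYPE, DRUG_MEAS, REGION, DV,
BLOQ`` (a NONMEM-like one-row-per-observation layout).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import DoseEvent
from .params import IIV_PARAMETERS, ModelParameters
from .simulate import simulate

__all__ = [
    "Observation",
    "StudyDesign",
    "default_study_designs",
    "sample_individual",
    "generate_dataset",
    "OBS_COLUMNS",
]

OBS_COLUMNS = ("STUDY", "ID", "DRUG_ADMIN", "ROUTE", "DOSE", "TIME", "TYPE",
               "DRUG_MEAS", "REGION", "DV", "BLOQ")

#: observation types
CONC_PLASMA = "conc_plasma"
CONC_BRAIN = "conc_brain"
RO_D2 = "ro_d2"
RO_5HT2A = "ro_5ht2a"


@dataclass(frozen=True)
class Observation:
    """One entry of a study's observation panel.

    ``obs_type`` is one of conc_plasma / conc_brain / ro_d2 / ro_5ht2a;
    ``drug`` names the measured analyte for concentrations (occupancy is the
    sum over both drugs and carries no analyte); ``region`` is the brain
    dissection variant for brain concentrations.
    """

    obs_type: str
    drug: str = ""
    region: str = ""


@dataclass(frozen=True)
class StudyDesign:
    """One arm-set of the destructive-sampling design table."""

    study: str
    drug: str                      # drug administered
    route: str
    doses: tuple                   # mg/kg
    times: tuple                   # h
    observations: tuple            # of Observation
    n_rats: int

    def cells(self) -> list:
        """(dose, time) cells in dose-major order."""
        return list(itertools.product(self.doses, self.times))

    def rats_per_cell(self, multiplier: int = 1) -> list:
        """Divide rats as evenly as possible; remainder to earliest cells."""
        cells = self.cells()
        n = self.n_rats * multiplier
        base, extra = divmod(n, len(cells))
        return [base + (1 if i < extra else 0) for i in range(len(cells))]


def _pc(drug):
    return Observation(CONC_PLASMA, drug)


def _bc(drug, region):
    return Observation(CONC_BRAIN, drug, region)


def default_study_designs() -> list:
    """The twelve destructive-sampling study designs.

    Brain concentration in the occupancy studies is the homogenate of the
    brain minus the assayed region (striatum for D2, frontal cortex for
    5-HT2A); study 3 measured the striatum and cortex themselves; study 4
    (no occupancy) is carried as brain-minus-striatum.
    """
    t_iv = (0.12, 0.33, 1.0, 2.0, 4.0, 8.0)
    t3 = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    return [
        StudyDesign("1", "RIS", "IV", (2.5,), t_iv, (_pc("RIS"),), 3),
        StudyDesign("2", "RIS", "IV", (2.0,), t_iv[:5], (_pc("RIS"),), 4),
        StudyDesign("3a", "PALI", "SC", (5.0,), t3,
                    (_pc("PALI"), _bc("PALI", "striatum"),
                     _bc("PALI", "cortex")), 23),
        StudyDesign("3b", "RIS", "SC", (5.0,), t3,
                    (_pc("RIS"), _pc("PALI"),
                     _bc("RIS", "striatum"), _bc("PALI", "striatum"),
                     _bc("RIS", "cortex"), _bc("PALI", "cortex")), 23),
        StudyDesign("4", "RIS", "IP", (0.3, 3.0),
                    (0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 7.0),
                    (_pc("RIS"), _pc("PALI"),
                     _bc("RIS", "excl_striatum"),
                     _bc("PALI", "excl_striatum")), 42),
        StudyDesign("5", "RIS", "IP", (1.0,), (0.25, 0.5, 1.0, 1.5, 2.0),
                    (_pc("RIS"), _bc("RIS", "excl_striatum"),
                     Observation(RO_D2)), 20),
        StudyDesign("6", "RIS", "IP", (0.01, 0.03, 0.1, 0.3, 1.0, 3.0), (1.0,),
                    (_pc("RIS"), _bc("RIS", "excl_striatum"),
                     Observation(RO_D2)), 23),
        StudyDesign("7", "RIS", "SC", (0.16, 10.0),
                    (0.5, 1.0, 2.0, 4.0, 8.0, 24.0),
                    (_pc("RIS"), _bc("RIS", "excl_striatum"),
                     Observation(RO_D2)), 36),
        StudyDesign("8a", "PALI", "SC", (0.16, 0.63, 2.5, 10.0), (1.0,),
                    (Observation(RO_D2),), 12),
        StudyDesign("8b", "RIS", "SC", (0.04, 0.16, 0.63, 2.5, 10.0, 40.0),
                    (1.0,), (Observation(RO_D2),), 18),
        StudyDesign("9", "RIS", "IP", (0.01, 0.03, 0.1, 0.3, 1.0), (1.0,),
                    (_pc("RIS"), _bc("RIS", "excl_cortex"),
                     Observation(RO_5HT2A)), 19),
        StudyDesign("10", "RIS", "IP", (0.1,), (0.25, 0.5, 1.0, 1.5, 2.0),
                    (_pc("RIS"), _bc("RIS", "excl_cortex"),
                     Observation(RO_5HT2A)), 20),
        StudyDesign("11", "RIS", "IP", (0.01, 0.03, 0.1, 0.3, 1.0, 3.0),
                    (1.0,), (_pc("RIS"), Observation(RO_5HT2A)), 24),
        StudyDesign("12", "RIS", "IP", (0.1, 0.3, 0.8, 1.0), (1.0,),
                    (_pc("RIS"), Observation(RO_5HT2A)), 15),
    ]


def sample_individual(params: ModelParameters,
                      rng: "np.random.Generator | int") -> ModelParameters:
    """Draw one animal's parameters under the log-normal IIV model.

    Parameter p with CV c (%) becomes p * exp(eta), eta ~ N(0, omega^2),
    omega^2 = ln(1 + (c/100)^2); parameters with zero CV are unchanged.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    updates = {}
    for name in IIV_PARAMETERS:
        omega = params.iiv.omega(name)
        if omega > 0:
            eta = rng.normal(0.0, omega)
            updates[name] = getattr(params.plasma, name) * math.exp(eta)
    if not updates:
        return params
    # sampled bioavailabilities may exceed 1: the log-normal IIV model is
    # unbounded above and truncating it would bias pooled estimation, so the
    # population-parameter (0, 1] bound is not enforced on individual draws
    indiv = replace(params.plasma, **updates)
    return replace(params, plasma=indiv)


def _observe(res, obs: Observation, params: ModelParameters) -> float:
    if obs.obs_type == CONC_PLASMA:
        return float(res.plasma_conc(obs.drug)[-1])
    if obs.obs_type == CONC_BRAIN:
        return float(res.brain_conc(obs.region, obs.drug)[-1])
    ro_d2, ro_5 = res.occupancy()
    return float(ro_d2[-1] if obs.obs_type == RO_D2 else ro_5[-1])


def _sigma_for(obs: Observation, params: ModelParameters) -> float:
    e = params.error
    if obs.obs_type == CONC_PLASMA:
        return e.sigma_prop_plasma_R if obs.drug == "RIS" else e.sigma_prop_plasma_P
    if obs.obs_type == CONC_BRAIN:
        return e.sigma_prop_brain_R if obs.drug == "RIS" else e.sigma_prop_brain_P
    if obs.obs_type == RO_D2:
        return e.sigma_add_RO_D2
    return e.sigma_add_RO_5HT2A


def generate_dataset(designs: Sequence[StudyDesign],
                     params: ModelParameters,
                     seed: "int | np.random.Generator" = 0,
                     loq: Mapping[str, float] | None = None,
                     multiplier: int = 1,
                     rtol: float = 1e-6,
                     atol: float = 1e-9) -> pd.DataFrame:
    """Simulate an observation table under the destructive-sampling designs.

    Each animal gets its own parameter draw, is dosed at t = 0 and observed
    once, at its cell's time point. Concentration observations are
    y = yhat * exp(eps) with eps ~ N(0, sigma_prop^2); occupancies are
    y = yhat + eps with eps in percentage points and are deliberately not
    truncated to [0, 100] (truncation would bias the estimation likelihood).
    ``loq`` maps observation type -> limit (nM); values at or below it are
    flagged BLOQ, never dropped here. Deterministic under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    loq = dict(loq or {})
    has_iiv = any(params.iiv.omega(n) > 0 for n in params.iiv.cv_percent)
    rows = []
    animal_counter = itertools.count(1)
    for design in designs:
        per_cell = design.rats_per_cell(multiplier)
        for (dose, t_obs), n_animals in zip(design.cells(), per_cell):
            regimen = [DoseEvent(design.drug, design.route, dose)]
            cell_res = None
            if not has_iiv and n_animals:
                # all animals in the cell share the population parameters
                cell_res = simulate(params, regimen, np.array([t_obs]),
                                    rtol=rtol, atol=atol)
            for _ in range(n_animals):
                aid = next(animal_counter)
                if cell_res is not None:
                    indiv, res = params, cell_res
                else:
                    indiv = sample_individual(params, rng)
                    res = simulate(indiv, regimen, np.array([t_obs]),
                                   rtol=rtol, atol=atol)
                for obs in design.observations:
                    yhat = _observe(res, obs, indiv)
                    sigma = _sigma_for(obs, params)
                    if obs.obs_type in (CONC_PLASMA, CONC_BRAIN):
                        dv = yhat * math.exp(rng.normal(0.0, sigma)) \
                            if sigma > 0 else yhat
                    else:
                        dv = yhat + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
                    bloq = int(obs.obs_type in (CONC_PLASMA, CONC_BRAIN)
                               and obs.obs_type in loq
                               and dv <= loq[obs.obs_type])
                    rows.append((design.study, aid, design.drug, design.route,
                                 dose, t_obs, obs.obs_type, obs.drug,
                                 obs.region, dv, bloq))
    df = pd.DataFrame(rows, columns=list(OBS_COLUMNS))
    return df
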