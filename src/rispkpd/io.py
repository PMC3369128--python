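"""Readers and writers: observation tables (NONMEM-like CSV), parameter
configuration files (YAML), and fit reports (JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .datasets import OBS_COLUMNS
from .params import (BrainParameters, ErrorModel, IIVModel, ModelParameters,
                     PhysiologicalConstants, PlasmaParameters)

__all__ = [
    "read_observations",
    "write_observations",
    "load_parameters",
    "save_parameters",
    "save_fit_report",
]

_OBS_TYPES = {"conc_plasma", "conc_brain", "ro_d2", "ro_5ht2a"}


class SchemaError(ValueError):
    """Raised when a file does not match the documented layout."""


def write_observations(table: pd.DataFrame, path) -> None:
    """Write an observation table as CSV (comma, UTF-8, '.' decimal)."""
    missing = set(OBS_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    table.loc[:, list(OBS_COLUMNS)].to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observation-table CSV.

    Checks the documented header, numeric DV / non-negative TIME, known
    observation types, uniqueness of (ID, TYPE, DRUG_MEAS, REGION) rows and
    the destructive-sampling invariant (one time point per animal).
    Below-LOQ rows are retained with their flag; estimation excludes them.
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    extra = set(df.columns) - set(OBS_COLUMNS)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if extra or missing:
        raise SchemaError(
            f"header mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
    df["STUDY"] = df["STUDY"].astype(str)
    for col in ("DRUG_MEAS", "REGION"):
        df[col] = df[col].fillna("").astype(str)
    for col, typ in (("DOSE", float), ("TIME", float), ("DV", float),
                     ("BLOQ", int)):
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric value in column {col}: {exc}")
    bad_time = df.index[df["TIME"] < 0]
    if len(bad_time):
        raise SchemaError(f"negative TIME at row {bad_time[0]}")
    bad_type = df.index[~df["TYPE"].isin(_OBS_TYPES)]
    if len(bad_type):
        raise SchemaError(
            f"unknown TYPE {df.loc[bad_type[0], 'TYPE']!r} at row {bad_type[0]}")
    dup = df.duplicated(subset=["ID", "TIME", "TYPE", "DRUG_MEAS", "REGION"])
    if dup.any():
        raise SchemaError(
            f"duplicate animal-time-type row at index {df.index[dup][0]}")
    times_per_id = df.groupby("ID")["TIME"].nunique()
    offenders = times_per_id[times_per_id > 1]
    if len(offenders):
        raise SchemaError(
            f"animal {offenders.index[0]} observed at multiple time points "
            "(destructive sampling allows exactly one)")
    return df


# ---------------------------------------------------------------------------
# Parameter configuration
# ---------------------------------------------------------------------------

_SECTIONS = {
    "physiological": PhysiologicalConstants,
    "plasma": PlasmaParameters,
    "brain": BrainParameters,
    "error": ErrorModel,
}

# Table-style aliases: drug suffixes spelled out
_ALIASES = {}
for cls in _SECTIONS.values():
    for f in dataclasses.fields(cls):
        if f.name.endswith("_R"):
            _ALIASES[f.name[:-2] + "_RIS"] = f.name
        elif f.name.endswith("_P"):
            _ALIASES[f.name[:-2] + "_PALI"] = f.name


def _field_names(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def load_parameters(path) -> ModelParameters:
    """Load a YAML parameter file; missing fields fall back to the published
    defaults, every invariant is checked.

    Layout: optional sections ``physiological``, ``plasma``, ``brain``,
    ``error`` and ``iiv`` (parameter -> %CV). Field names are the canonical
    ones (``Ka_SC_R``); spelled-out drug suffixes (``Ka_SC_RIS``) are
    accepted as aliases. Top-level keys outside the sections are resolved
    against all sections, rejecting ambiguity.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, Mapping):
        raise SchemaError("parameter file must be a mapping")
    sections: dict = {name: {} for name in _SECTIONS}
    iiv = None
    for key, value in raw.items():
        if key in _SECTIONS:
            if not isinstance(value, Mapping):
                raise SchemaError(f"section {key!r} must be a mapping")
            for k, v in value.items():
                k = _ALIASES.get(k, k)
                if k not in _field_names(_SECTIONS[key]):
                    raise SchemaError(f"unknown field {k!r} in section {key!r}")
                sections[key][k] = float(v)
        elif key == "iiv":
            if not isinstance(value, Mapping):
                raise SchemaError("section 'iiv' must be a mapping")
            iiv = {str(k): float(v) for k, v in value.items()}
        else:
            name = _ALIASES.get(key, key)
            homes = [s for s, cls in _SECTIONS.items()
                     if name in _field_names(cls)]
            if not homes:
                raise SchemaError(f"unknown parameter {key!r}")
            if len(homes) > 1:
                raise SchemaError(f"ambiguous parameter {key!r}: {homes}")
            sections[homes[0]][name] = float(value)
    params = ModelParameters(
        physiological=PhysiologicalConstants(**sections["physiological"]),
        plasma=PlasmaParameters(**sections["plasma"]),
        brain=BrainParameters(**sections["brain"]),
        error=ErrorModel(**sections["error"]),
        iiv=IIVModel(cv_percent=iiv) if iiv is not None else IIVModel(),
    )
    try:
        params.validate()
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc
    return params


def save_parameters(params: ModelParameters, path) -> None:
    doc = {
        "physiological": dataclasses.asdict(params.physiological),
        "plasma": dataclasses.asdict(params.plasma),
        "brain": dataclasses.asdict(params.brain),
        "error": dataclasses.asdict(params.error),
        "iiv": dict(params.iiv.cv_percent),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def save_fit_report(fit, path) -> None:
    """Serialize a FitResult (or any mapping) as JSON."""
    obj = fit.to_dict() if hasattr(fit, "to_dict") else dict(fit)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
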