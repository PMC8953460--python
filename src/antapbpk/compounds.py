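"""Compound parameter types and built-in antazoline / hydroxyantazoline fixtures.

The PBPK workflow is parameterized per analyte by a small set of
physico-chemical, blood-binding and elimination inputs (molecular weight,
logP, pKa, fu, B/P, pathway-level intrinsic clearances).  This module defines
the validated containers for those inputs, a YAML loader with canonical
units (g/mol, L/h, µL/min/pmol), and the packaged parameter sets for
antazoline (monoprotic base) and its hydroxy metabolite (ampholyte).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "PKaEntry",
    "EnzymePathway",
    "EliminationSpec",
    "CompoundParameters",
    "InVitroPanel",
    "AssayValue",
    "load_compound",
    "load_panel",
    "builtin_fixtures",
    "antazoline",
    "hydroxyantazoline",
    "antazoline_invitro_panel",
    "MESYLATE_SALT_FACTOR",
]

#: Free-base / mesylate-salt molecular weight ratio for antazoline
#: (265.35 / 361.46).  Clinical doses are stated as mg of the mesylate salt;
#: multiplying by this factor gives mg of free base entering the model.
MESYLATE_SALT_FACTOR = 265.35 / 361.46


class PKaEntry(BaseModel):
    """One dissociation constant with its acid/base role."""

    model_config = ConfigDict(frozen=True)

    value: float = Field(gt=0, lt=16)
    role: Literal["acid", "base"]


class EnzymePathway(BaseModel):
    """A single CYP pathway: recombinant CLint plus IVIVE metadata.

    ``clint_per_pmol`` is the recombinant-enzyme intrinsic clearance in
    µL/min/pmol isoform; ``isef`` is the inter-system extrapolation factor
    applied during scaling; ``metabolite_fraction`` is the fraction of this
    pathway's turnover that forms the tracked metabolite.
    """

    model_config = ConfigDict(frozen=True)

    enzyme: str
    clint_per_pmol: float = Field(ge=0)  # µL/min/pmol isoform
    isef: float = Field(default=1.0, gt=0)
    metabolite_fraction: float = Field(default=0.0, ge=0.0, le=1.0)


class EliminationSpec(BaseModel):
    """Elimination inputs: CYP pathways and/or lumped systemic clearance (L/h)."""

    model_config = ConfigDict(frozen=True)

    enzyme_pathways: tuple[EnzymePathway, ...] = ()
    additional_systemic_clearance: float = Field(default=0.0, ge=0)  # L/h, plasma
    total_systemic_clearance: Optional[float] = Field(default=None, ge=0)  # L/h

    @property
    def has_enzymatic(self) -> bool:
        return any(p.clint_per_pmol > 0 for p in self.enzyme_pathways)


class CompoundParameters(BaseModel):
    """Validated per-analyte model inputs in canonical units."""

    model_config = ConfigDict(frozen=True)

    name: str
    ionization_class: Literal["monoprotic_base", "ampholyte", "neutral"]
    molecular_weight: float = Field(gt=0)  # g/mol
    logP: float
    pKa_values: tuple[PKaEntry, ...] = ()
    fu_plasma: float = Field(gt=0, le=1)
    blood_plasma_ratio: float = Field(gt=0)
    fu_mic: float = Field(default=1.0, gt=0, le=1)
    elimination: EliminationSpec = EliminationSpec()
    vss_override: Optional[float] = Field(default=None, gt=0)  # L/kg

    @model_validator(mode="after")
    def _check_pka_roles(self) -> "CompoundParameters":
        acids = [p for p in self.pKa_values if p.role == "acid"]
        bases = [p for p in self.pKa_values if p.role == "base"]
        if self.ionization_class == "monoprotic_base":
            if len(bases) != 1 or acids:
                raise ValueError(
                    "pKa_values: monoprotic_base requires exactly one base pKa"
                )
        elif self.ionization_class == "ampholyte":
            if len(acids) != 1 or len(bases) != 1:
                raise ValueError(
                    "pKa_values: ampholyte requires exactly one acid and one base pKa"
                )
        elif self.ionization_class == "neutral" and self.pKa_values:
            raise ValueError("pKa_values: neutral compound must not declare pKa values")
        return self

    @property
    def acid_pka(self) -> Optional[float]:
        for p in self.pKa_values:
            if p.role == "acid":
                return p.value
        return None

    @property
    def base_pka(self) -> Optional[float]:
        for p in self.pKa_values:
            if p.role == "base":
                return p.value
        return None


class AssayValue(BaseModel):
    """One in vitro assay result: value, dispersion (SD or SE) and units."""

    model_config = ConfigDict(frozen=True)

    value: float = Field(ge=0)
    dispersion: float = Field(default=0.0, ge=0)
    units: str


class InVitroPanel(BaseModel):
    """Lookup from assay label to measured value (blood binding + metabolism)."""

    model_config = ConfigDict(frozen=True)

    compound: str
    assays: dict[str, AssayValue]

    def __getitem__(self, label: str) -> AssayValue:
        return self.assays[label]

    def __contains__(self, label: str) -> bool:
        return label in self.assays


def _data_path(filename: str) -> Path:
    return Path(str(importlib.resources.files("antapbpk") / "data" / filename))


def load_compound(source: str | Path | dict) -> CompoundParameters:
    """Load and validate a compound parameter document (YAML path or mapping).

    Canonical units are g/mol, L/h and µL/min/pmol; documents must already be
    expressed in them.  Validation failures name the offending field.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, dict):
        raise ValueError("compound document must be a mapping")
    return CompoundParameters.model_validate(doc)


def save_compound(compound: CompoundParameters, path: str | Path) -> None:
    """Serialize a compound document back to YAML (round-trip safe)."""
    with open(path, "w") as fh:
        yaml.safe_dump(compound.model_dump(mode="json"), fh, sort_keys=False)


def load_panel(source: str | Path | dict) -> InVitroPanel:
    """Load an in vitro assay panel document."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    return InVitroPanel.model_validate(doc)


def antazoline() -> CompoundParameters:
    """Packaged antazoline parameter set (free base)."""
    return load_compound(_data_path("antazoline.yaml"))


def hydroxyantazoline() -> CompoundParameters:
    """Packaged hydroxyantazoline (M2) parameter set."""
    return load_compound(_data_path("hydroxyantazoline.yaml"))


def antazoline_invitro_panel() -> InVitroPanel:
    """Packaged antazoline in vitro binding / metabolic-stability panel."""
    return load_panel(_data_path("antazoline_invitro.yaml"))


def builtin_fixtures() -> dict[str, CompoundParameters | InVitroPanel]:
    """All packaged fixtures keyed by name."""
    return {
        "antazoline": antazoline(),
        "hydroxyantazoline": hydroxyantazoline(),
        "antazoline_invitro": antazoline_invitro_panel(),
    }
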