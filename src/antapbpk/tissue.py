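"""Mechanistic tissue:plasma partitioning (Rodgers-Rowland) and Vss.

Implements the Rodgers-Rowland tissue-composition equations for predicting
steady-state tissue:plasma partition coefficients (Kp) of ionizable drugs.
Moderate-to-strong bases — and ampholytes carrying a strong basic group —
partition into tissue water, neutral lipids/phospholipids and, as cations,
onto intracellular acidic phospholipids; the acidic-phospholipid association
constant is calibrated from the measured blood:plasma ratio via erythrocyte
partitioning.  Neutral species instead carry an albumin-binding term derived
from the plasma unbound fraction.

The steady-state volume of distribution follows as the Kp-weighted sum of
organ volumes plus plasma and erythrocyte terms, normalized by body weight.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .compounds import CompoundParameters, PKaEntry

__all__ = [
    "TissueComposition",
    "KpSet",
    "load_tissue_compositions",
    "ionized_fractions",
    "acidic_phospholipid_ka",
    "predict_kp",
    "predict_kp_set",
    "compute_vss",
    "PERFUSED_TISSUES",
]

#: Perfused (non-blood) compartments of the whole-body model.
PERFUSED_TISSUES = (
    "adipose", "bone", "brain", "gut", "heart", "kidney",
    "liver", "lung", "muscle", "pancreas", "skin", "spleen",
)

PLASMA_PH = 7.4


@dataclass(frozen=True)
class TissueComposition:
    """Composition of one tissue as used by the partitioning equations."""

    tissue: str
    f_water_extra: float       # fractional volume, extracellular water
    f_water_intra: float       # fractional volume, intracellular water
    f_neutral_lipid: float
    f_neutral_phospholipid: float
    acidic_phospholipid_conc: float  # mg/g tissue
    albumin_ratio: float       # tissue:plasma albumin concentration ratio
    intracellular_pH: float
    extracellular_pH: float = PLASMA_PH

    def __post_init__(self) -> None:
        for name in ("f_water_extra", "f_water_intra", "f_neutral_lipid",
                     "f_neutral_phospholipid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.tissue}: {name}={v} outside [0, 1]")
        if not 6.0 <= self.intracellular_pH <= 8.0:
            raise ValueError(f"{self.tissue}: intracellular pH outside [6, 8]")
        if self.acidic_phospholipid_conc < 0:
            raise ValueError(f"{self.tissue}: negative acidic phospholipid")


@dataclass(frozen=True)
class KpSet:
    """Tissue:plasma partition coefficients plus blood-side ratios."""

    kps: Mapping[str, float]
    method: str = "rodgers-rowland"
    erythrocyte_plasma_ratio: float = 1.0

    def __post_init__(self) -> None:
        for tissue, kp in self.kps.items():
            if kp <= 0:
                raise ValueError(f"Kp for {tissue} must be > 0, got {kp}")

    def __getitem__(self, tissue: str) -> float:
        return self.kps[tissue]

    def __contains__(self, tissue: str) -> bool:
        return tissue in self.kps


def _composition_path() -> Path:
    return Path(str(importlib.resources.files("antapbpk") / "data"
                    / "tissue_composition.csv"))


def load_tissue_compositions(
    path: str | Path | None = None,
) -> dict[str, TissueComposition]:
    """Load the packaged (or user-override) tissue-composition table.

    The table must provide the documented header; rows ``blood_cells`` and
    ``plasma`` parameterize the erythrocyte calibration and the plasma lipid
    content respectively.
    """
    df = pd.read_csv(path or _composition_path(), comment="#")
    out: dict[str, TissueComposition] = {}
    for row in df.itertuples(index=False):
        out[row.tissue] = TissueComposition(
            tissue=row.tissue,
            f_water_extra=row.f_water_extra,
            f_water_intra=row.f_water_intra,
            f_neutral_lipid=row.f_neutral_lipid,
            f_neutral_phospholipid=row.f_neutral_phospholipid,
            acidic_phospholipid_conc=row.acidic_phospholipid_mg_g,
            albumin_ratio=row.albumin_ratio,
            intracellular_pH=row.pH_intra,
        )
    return out


def ionized_fractions(
    pKa_values: Iterable[PKaEntry],
    ionization_class: str,
    pH: float,
) -> dict[str, float]:
    """Henderson-Hasselbalch species fractions at a given pH.

    Returns fractions of net-neutral, cationic and anionic species (summing
    to one).  Ampholytes are treated as two independent sites; the doubly
    charged species is neglected, and the zwitterion counts as net-neutral.
    """
    pkas = tuple(pKa_values)
    if ionization_class == "neutral":
        return {"neutral": 1.0, "cationic": 0.0, "anionic": 0.0}
    if ionization_class == "monoprotic_base":
        (base,) = [p.value for p in pkas if p.role == "base"]
        cat = 10.0 ** (base - pH)
        denom = 1.0 + cat
        return {"neutral": 1.0 / denom, "cationic": cat / denom, "anionic": 0.0}
    if ionization_class == "ampholyte":
        (base,) = [p.value for p in pkas if p.role == "base"]
        (acid,) = [p.value for p in pkas if p.role == "acid"]
        cat = 10.0 ** (base - pH)
        ani = 10.0 ** (pH - acid)
        denom = 1.0 + cat + ani
        return {"neutral": 1.0 / denom, "cationic": cat / denom,
                "anionic": ani / denom}
    raise ValueError(f"unsupported ionization class: {ionization_class!r}")


def _ionization_terms(compound: CompoundParameters, pH: float) -> tuple[float, float]:
    """Return (total:neutral ratio X, cationic:neutral ratio) at ``pH``."""
    cls = compound.ionization_class
    if cls == "neutral":
        return 1.0, 0.0
    cat = 10.0 ** (compound.base_pka - pH) if compound.base_pka is not None else 0.0
    ani = 10.0 ** (pH - compound.acid_pka) if compound.acid_pka is not None else 0.0
    return 1.0 + cat + ani, cat


def _neutral_lipid_partition(logP: float) -> float:
    return 10.0 ** logP


def _vegetable_oil_partition(logP: float) -> float:
    # Empirical olive-oil:water regression for adipose neutral lipid.
    return 10.0 ** (1.115 * logP - 1.35)


def _lipid_term(p_nl: float, f_nl: float, f_np: float) -> float:
    return p_nl * f_nl + (0.3 * p_nl + 0.7) * f_np


def erythrocyte_plasma_ratio(blood_plasma_ratio: float, hematocrit: float) -> float:
    """Erythrocyte:plasma concentration ratio implied by B/P and hematocrit."""
    ep = (blood_plasma_ratio - (1.0 - hematocrit)) / hematocrit
    if ep < 0:
        raise ValueError(
            f"B/P {blood_plasma_ratio} < 1 - hematocrit ({1 - hematocrit:.2f}): "
            "negative erythrocyte concentration implied"
        )
    return ep


def acidic_phospholipid_ka(
    compound: CompoundParameters,
    blood_cells: TissueComposition,
    hematocrit: float = 0.45,
) -> float:
    """Cation/acidic-phospholipid association constant from erythrocyte data.

    Back-calculated from the measured blood:plasma ratio: erythrocyte
    partitioning in excess of intracellular-water trapping and passive lipid
    partitioning is attributed to electrostatic binding of the cationic
    species to erythrocyte acidic phospholipids.  If the measured B/P is at
    or below the passive prediction the constant is clamped to zero (no
    detectable acidic-phospholipid binding) with a warning.
    """
    ep = erythrocyte_plasma_ratio(compound.blood_plasma_ratio, hematocrit)
    kpu_bc = ep / compound.fu_plasma
    y_plasma, _ = _ionization_terms(compound, PLASMA_PH)
    x_bc, cat_bc = _ionization_terms(compound, blood_cells.intracellular_pH)
    if cat_bc <= 0:
        raise ValueError("acidic-phospholipid Ka requires a basic pKa")
    p_nl = _neutral_lipid_partition(compound.logP)
    passive = (
        blood_cells.f_water_intra * x_bc / y_plasma
        + _lipid_term(p_nl, blood_cells.f_neutral_lipid,
                      blood_cells.f_neutral_phospholipid) / y_plasma
    )
    residual = kpu_bc - passive
    if residual < 0:
        warnings.warn(
            f"{compound.name}: measured B/P below passive erythrocyte "
            "partitioning; acidic-phospholipid Ka clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return residual * y_plasma / (blood_cells.acidic_phospholipid_conc * cat_bc)


def _uses_acidic_phospholipid_binding(compound: CompoundParameters) -> bool:
    return compound.base_pka is not None and compound.base_pka >= 7.0


def predict_kp(
    compound: CompoundParameters,
    composition: TissueComposition,
    *,
    plasma: Optional[TissueComposition] = None,
    blood_cells: Optional[TissueComposition] = None,
    hematocrit: float = 0.45,
    ka_ap: Optional[float] = None,
    adipose_vegetable_oil: bool = False,
) -> float:
    """Predict one tissue:plasma partition coefficient (Kp).

    Moderate-to-strong bases and strong-base ampholytes use the
    acidic-phospholipid equation (``ka_ap`` may be precomputed via
    :func:`acidic_phospholipid_ka`; otherwise it is derived here from B/P).
    Neutral species (and ampholytes with no basic group above pH 7) use the
    albumin-binding equation.  ``adipose_vegetable_oil`` switches the adipose
    neutral-lipid phase to an olive-oil:water coefficient regressed from
    logP; the default applies logP o:w uniformly, matching the way the model
    is parameterized from a single reported logP.
    """
    comps = None
    if plasma is None or blood_cells is None:
        comps = load_tissue_compositions()
        plasma = plasma or comps["plasma"]
        blood_cells = blood_cells or comps["blood_cells"]

    if adipose_vegetable_oil and composition.tissue == "adipose":
        p_nl = _vegetable_oil_partition(compound.logP)
    else:
        p_nl = _neutral_lipid_partition(compound.logP)
    p_nl_plasma = _neutral_lipid_partition(compound.logP)

    y_plasma, _ = _ionization_terms(compound, PLASMA_PH)
    x_t, cat_t = _ionization_terms(compound, composition.intracellular_pH)
    lipid = _lipid_term(p_nl, composition.f_neutral_lipid,
                        composition.f_neutral_phospholipid)

    kpu = (
        composition.f_water_extra
        + composition.f_water_intra * x_t / y_plasma
        + lipid / y_plasma
    )
    if _uses_acidic_phospholipid_binding(compound):
        if ka_ap is None:
            ka_ap = acidic_phospholipid_ka(compound, blood_cells, hematocrit)
        kpu += ka_ap * composition.acidic_phospholipid_conc * cat_t / y_plasma
    else:
        lipid_plasma = _lipid_term(p_nl_plasma, plasma.f_neutral_lipid,
                                   plasma.f_neutral_phospholipid)
        protein = (1.0 / compound.fu_plasma - 1.0 - lipid_plasma / y_plasma)
        kpu += max(protein, 0.0) * composition.albumin_ratio

    kp = kpu * compound.fu_plasma
    if kp <= 0:
        raise ValueError(f"non-positive Kp predicted for {composition.tissue}")
    return kp


def predict_kp_set(
    compound: CompoundParameters,
    compositions: Optional[Mapping[str, TissueComposition]] = None,
    *,
    hematocrit: float = 0.45,
    adipose_vegetable_oil: bool = False,
    tissues: Iterable[str] = PERFUSED_TISSUES,
) -> KpSet:
    """Predict Kp for every perfused tissue of the whole-body model."""
    comps = dict(compositions) if compositions is not None \
        else load_tissue_compositions()
    plasma = comps["plasma"]
    blood_cells = comps["blood_cells"]
    ka_ap = (
        acidic_phospholipid_ka(compound, blood_cells, hematocrit)
        if _uses_acidic_phospholipid_binding(compound) else None
    )
    kps = {
        t: predict_kp(
            compound, comps[t], plasma=plasma, blood_cells=blood_cells,
            hematocrit=hematocrit, ka_ap=ka_ap,
            adipose_vegetable_oil=adipose_vegetable_oil,
        )
        for t in tissues
    }
    return KpSet(
        kps=kps,
        method="rodgers-rowland",
        erythrocyte_plasma_ratio=erythrocyte_plasma_ratio(
            compound.blood_plasma_ratio, hematocrit),
    )


def compute_vss(kps: KpSet, subject, compound: CompoundParameters) -> float:
    """Steady-state volume of distribution (plasma-referenced), L/kg.

    Vss = (V_plasma + Σ_T V_T·Kp_T + V_ery·E:P) / body weight, where E:P is
    the erythrocyte:plasma ratio implied by the compound's B/P and the
    subject's hematocrit.  ``subject`` must expose ``organ_volumes`` (L),
    ``blood_volume`` (L), ``hematocrit`` and ``body_weight`` (kg).
    """
    missing = [t for t in subject.organ_volumes if t not in kps]
    if missing:
        raise KeyError(f"KpSet missing tissues: {', '.join(sorted(missing))}")
    v_plasma = subject.blood_volume * (1.0 - subject.hematocrit)
    v_ery = subject.blood_volume * subject.hematocrit
    ep = erythrocyte_plasma_ratio(compound.blood_plasma_ratio,
                                  subject.hematocrit)
    v_tissues = sum(v * kps[t] for t, v in subject.organ_volumes.items())
    return (v_plasma + v_tissues + v_ery * ep) / subject.body_weight


def kp_report(kps: KpSet) -> pd.DataFrame:
    """Tabular Kp report (tissue, Kp, method)."""
    return pd.DataFrame(
        {"tissue": list(kps.kps), "kp": list(kps.kps.values()),
         "method": kps.method}
    )
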