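"""In vitro-in vivo extrapolation of intrinsic clearance.

Recombinant-enzyme intrinsic clearances (µL/min/pmol isoform) are scaled to
whole-liver unbound intrinsic clearance through enzyme abundance, microsomal
protein yield (MPPGL) and liver mass, corrected by inter-system extrapolation
factors (ISEF), and converted to hepatic blood clearance with the
well-stirred liver model.  The module also partitions parent elimination
into metabolite-forming pathways and derives the non-CYP "additional"
systemic clearance as the clinical-minus-IVIVE clearance gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .compounds import CompoundParameters, EnzymePathway, InVitroPanel

__all__ = [
    "LiverScalars",
    "ClearanceBreakdown",
    "scale_pathway_clint",
    "well_stirred_hepatic_cl",
    "derive_additional_clearance",
    "build_clearance_breakdown",
    "formation_split",
    "hlm_crosscheck",
    "hepatocyte_crosscheck",
]

UL_PER_MIN_TO_L_PER_H = 60.0 / 1.0e6


@dataclass(frozen=True)
class LiverScalars:
    """IVIVE scalars for one individual's liver.

    Defaults are widely used reference values for a healthy adult
    (MPPGL 40 mg microsomal protein per g liver, 1650 g liver for an 81-kg
    adult, hepatic blood flow ~97 L/h, CYP abundances 8 / 14 pmol per mg
    microsomal protein for CYP2D6 / CYP2C19).
    """

    mppgl: float = 40.0            # mg microsomal protein / g liver
    liver_mass: float = 1650.0     # g
    hepatic_blood_flow: float = 96.725  # L/h
    enzyme_abundances: Mapping[str, float] = field(
        default_factory=lambda: {"CYP2D6": 8.0, "CYP2C19": 14.0}
    )

    def __post_init__(self) -> None:
        if min(self.mppgl, self.liver_mass, self.hepatic_blood_flow) <= 0:
            raise ValueError("liver scalars must be positive")
        if any(a < 0 for a in self.enzyme_abundances.values()):
            raise ValueError("enzyme abundances must be non-negative")


@dataclass(frozen=True)
class ClearanceBreakdown:
    """Clearance decomposition feeding the whole-body model.

    ``pathway_clint_u`` are unbound whole-liver intrinsic clearances (L/h);
    ``hepatic_blood_cl`` is the well-stirred hepatic blood clearance;
    ``hepatic_plasma_cl`` its plasma-referenced equivalent (× B/P);
    ``additional_plasma_cl`` the venous non-CYP clearance; totals are
    plasma-referenced.  ``formation_fractions`` give, per tracked-metabolite
    pathway, the fraction of *total* parent elimination forming it.
    """

    pathway_clint_u: Mapping[str, float]   # L/h per enzyme
    hepatic_blood_cl: float                # L/h
    hepatic_plasma_cl: float               # L/h
    additional_plasma_cl: float            # L/h
    total_plasma_cl: float                 # L/h
    formation_fractions: Mapping[str, float]
    metabolite_fraction_of_clint: float    # Σ share_i · mf_i over hepatic CLint

    def __post_init__(self) -> None:
        total = sum(self.formation_fractions.values())
        if not -1e-9 <= total <= 1.0 + 1e-9:
            raise ValueError("formation fractions must sum to ≤ 1")

    @property
    def clint_u_total(self) -> float:
        return sum(self.pathway_clint_u.values())

    @property
    def metabolite_formation_fraction(self) -> float:
        """Fraction of total parent elimination forming the tracked metabolite."""
        return sum(self.formation_fractions.values())


def scale_pathway_clint(pathway: EnzymePathway, scalars: LiverScalars) -> float:
    """Whole-liver unbound intrinsic clearance for one CYP pathway, L/h.

    CLint,u = CLint[µL/min/pmol] · ISEF · abundance[pmol/mg] · MPPGL[mg/g]
    · liver mass[g], converted to L/h.
    """
    try:
        abundance = scalars.enzyme_abundances[pathway.enzyme]
    except KeyError:
        raise KeyError(
            f"no abundance configured for enzyme {pathway.enzyme!r}"
        ) from None
    ul_per_min = (pathway.clint_per_pmol * pathway.isef * abundance
                  * scalars.mppgl * scalars.liver_mass)
    return ul_per_min * UL_PER_MIN_TO_L_PER_H


def well_stirred_hepatic_cl(
    clint_u_total: float,
    fu_plasma: float,
    blood_plasma_ratio: float,
    hepatic_blood_flow: float,
) -> float:
    """Well-stirred hepatic blood clearance, L/h.

    CLH = Q_H · fu_B · CLint,u / (Q_H + fu_B · CLint,u), with
    fu_B = fu_plasma / (B/P).  Bounded by hepatic blood flow.
    """
    if min(fu_plasma, blood_plasma_ratio, hepatic_blood_flow) <= 0:
        raise ValueError("fu, B/P and hepatic blood flow must be positive")
    if clint_u_total < 0:
        raise ValueError("intrinsic clearance must be non-negative")
    fu_b = fu_plasma / blood_plasma_ratio
    num = fu_b * clint_u_total
    return hepatic_blood_flow * num / (hepatic_blood_flow + num)


def derive_additional_clearance(
    clinical_total_cl: float,
    scaled_cyp_cl: float,
    *,
    rounding: Optional[int] = None,
) -> float:
    """Additional (non-CYP) systemic clearance = clinical minus IVIVE, L/h.

    ``rounding`` optionally rounds to the given number of significant
    figures, matching how a rounded value would be carried as a model input.
    """
    if scaled_cyp_cl < 0 or clinical_total_cl < scaled_cyp_cl:
        raise ValueError(
            "clinical clearance must be ≥ scaled CYP clearance ≥ 0 "
            f"(got {clinical_total_cl} and {scaled_cyp_cl})"
        )
    diff = clinical_total_cl - scaled_cyp_cl
    if rounding is not None and diff > 0:
        from math import floor, log10
        digits = rounding - 1 - floor(log10(abs(diff)))
        diff = round(diff, digits)
    return diff


def build_clearance_breakdown(
    compound: CompoundParameters,
    scalars: LiverScalars,
) -> ClearanceBreakdown:
    """Full clearance decomposition for a compound under given liver scalars."""
    pathway_clint = {
        p.enzyme: scale_pathway_clint(p, scalars)
        for p in compound.elimination.enzyme_pathways
    }
    clint_total = sum(pathway_clint.values())
    cl_h_blood = well_stirred_hepatic_cl(
        clint_total, compound.fu_plasma, compound.blood_plasma_ratio,
        scalars.hepatic_blood_flow,
    ) if clint_total > 0 else 0.0
    cl_h_plasma = cl_h_blood * compound.blood_plasma_ratio
    cl_add = compound.elimination.additional_systemic_clearance
    if not pathway_clint and compound.elimination.total_systemic_clearance:
        cl_add = cl_add + compound.elimination.total_systemic_clearance
    total = cl_h_plasma + cl_add

    formation: dict[str, float] = {}
    mf_of_clint = 0.0
    if clint_total > 0 and total > 0:
        for p in compound.elimination.enzyme_pathways:
            share = pathway_clint[p.enzyme] / clint_total
            mf_of_clint += share * p.metabolite_fraction
            formation[p.enzyme] = (
                p.metabolite_fraction * pathway_clint[p.enzyme] / clint_total
                * cl_h_plasma / total
            )
    return ClearanceBreakdown(
        pathway_clint_u=pathway_clint,
        hepatic_blood_cl=cl_h_blood,
        hepatic_plasma_cl=cl_h_plasma,
        additional_plasma_cl=cl_add,
        total_plasma_cl=total,
        formation_fractions=formation,
        metabolite_fraction_of_clint=mf_of_clint,
    )


def formation_split(breakdown: ClearanceBreakdown) -> float:
    """Fraction of total parent elimination forming the tracked metabolite."""
    return breakdown.metabolite_formation_fraction


def hlm_crosscheck(
    panel: InVitroPanel,
    scalars: LiverScalars,
    fu_plasma: float,
    blood_plasma_ratio: float,
) -> dict[str, float]:
    """Diagnostic hepatic clearance from HLM CLint with fu(mic) correction.

    CLint,u = (CLint,HLM / fu_mic) · MPPGL · liver mass, then well-stirred.
    Reported alongside the recombinant-based estimate; not used by the model.
    """
    clint_hlm = panel["hlm_clint"].value           # µL/min/mg protein
    fu_mic = panel["fu_mic"].value if "fu_mic" in panel else 1.0
    clint_u_per_mg = clint_hlm / fu_mic
    clint_u = (clint_u_per_mg * scalars.mppgl * scalars.liver_mass
               * UL_PER_MIN_TO_L_PER_H)
    cl_h = well_stirred_hepatic_cl(
        clint_u, fu_plasma, blood_plasma_ratio, scalars.hepatic_blood_flow)
    return {"clint_u_per_mg": clint_u_per_mg, "clint_u_liver": clint_u,
            "hepatic_blood_cl": cl_h,
            "hepatic_plasma_cl": cl_h * blood_plasma_ratio}


def hepatocyte_crosscheck(
    panel: InVitroPanel,
    scalars: LiverScalars,
    fu_plasma: float,
    blood_plasma_ratio: float,
    hepatocellularity: float = 120.0,  # 10^6 cells / g liver
) -> dict[str, float]:
    """Diagnostic hepatic clearance from the hepatocyte CLint assay."""
    clint = panel["hepatocyte_clint"].value        # µL/min/10^6 cells
    clint_u = (clint * hepatocellularity * scalars.liver_mass
               * UL_PER_MIN_TO_L_PER_H)
    cl_h = well_stirred_hepatic_cl(
        clint_u, fu_plasma, blood_plasma_ratio, scalars.hepatic_blood_flow)
    return {"clint_u_liver": clint_u, "hepatic_blood_cl": cl_h,
            "hepatic_plasma_cl": cl_h * blood_plasma_ratio}
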