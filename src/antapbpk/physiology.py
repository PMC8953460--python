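"""Reference adult physiology for the whole-body model.

Organ volumes, regional blood flows and liver IVIVE scalars for a healthy
81-kg European adult male.  All perfused tissues of the model receive an
explicit flow fraction; the fractions sum to one so that regional flows sum
to cardiac output (the lung is in series and carries the full cardiac
output).  Gut, spleen and pancreas drain through the portal vein into the
liver, whose total inflow is the hepatic artery plus the splanchnic
outflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .ivive import LiverScalars

__all__ = [
    "VirtualSubject",
    "reference_subject",
    "REFERENCE_BODY_WEIGHT",
    "REFERENCE_ORGAN_VOLUME_FRACTIONS",
    "REFERENCE_FLOW_FRACTIONS",
    "SPLANCHNIC_TISSUES",
]

REFERENCE_BODY_WEIGHT = 81.0   # kg
REFERENCE_CARDIAC_OUTPUT = 365.0  # L/h (~6.1 L/min)
REFERENCE_BLOOD_VOLUME = 5.6   # L
REFERENCE_HEMATOCRIT = 0.45

#: Organ volumes (L) for the 81-kg reference adult.
REFERENCE_ORGAN_VOLUMES: dict[str, float] = {
    "adipose": 17.0,
    "bone": 8.5,
    "brain": 1.45,
    "gut": 1.65,
    "heart": 0.33,
    "kidney": 0.31,
    "liver": 1.65,
    "lung": 0.50,
    "muscle": 29.0,
    "pancreas": 0.10,
    "skin": 2.60,
    "spleen": 0.19,
}
REFERENCE_ORGAN_VOLUME_FRACTIONS = {
    t: v / REFERENCE_BODY_WEIGHT for t, v in REFERENCE_ORGAN_VOLUMES.items()
}

#: Fractions of cardiac output; "liver" is the hepatic artery only.
REFERENCE_FLOW_FRACTIONS: dict[str, float] = {
    "adipose": 0.050,
    "bone": 0.050,
    "brain": 0.120,
    "gut": 0.160,
    "heart": 0.040,
    "kidney": 0.190,
    "liver": 0.065,
    "muscle": 0.170,
    "pancreas": 0.010,
    "skin": 0.115,
    "spleen": 0.030,
}

#: Tissues whose venous outflow enters the liver (portal drainage).
SPLANCHNIC_TISSUES = ("gut", "spleen", "pancreas")

#: Fraction of blood volume assigned to the venous pool (rest arterial).
VENOUS_BLOOD_FRACTION = 0.7


@dataclass(frozen=True)
class VirtualSubject:
    """One individual's physiology as consumed by the model builders."""

    id: str
    sex: str
    age: float
    body_weight: float                  # kg
    organ_volumes: Mapping[str, float]  # L per tissue
    blood_flows: Mapping[str, float]    # L/h per tissue ("liver" = hepatic artery)
    cardiac_output: float               # L/h
    blood_volume: float                 # L
    hematocrit: float
    liver: LiverScalars
    cyp_phenotypes: Mapping[str, str] = field(default_factory=dict)
    clearance_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        flow_sum = sum(self.blood_flows.values())
        if abs(flow_sum - self.cardiac_output) > 1e-3 * self.cardiac_output:
            raise ValueError(
                f"subject {self.id}: tissue flows sum to {flow_sum:.2f} L/h, "
                f"cardiac output is {self.cardiac_output:.2f} L/h"
            )
        if any(v <= 0 for v in self.organ_volumes.values()):
            raise ValueError(f"subject {self.id}: non-positive organ volume")
        if not 0.2 <= self.hematocrit <= 0.6:
            raise ValueError(f"subject {self.id}: implausible hematocrit")

    @property
    def venous_blood_volume(self) -> float:
        return self.blood_volume * VENOUS_BLOOD_FRACTION

    @property
    def arterial_blood_volume(self) -> float:
        return self.blood_volume * (1.0 - VENOUS_BLOOD_FRACTION)

    @property
    def liver_inflow(self) -> float:
        """Total liver blood inflow: hepatic artery + portal drainage, L/h."""
        return self.blood_flows["liver"] + sum(
            self.blood_flows[t] for t in SPLANCHNIC_TISSUES)


def reference_subject(
    body_weight: float = REFERENCE_BODY_WEIGHT,
    *,
    subject_id: str = "reference",
    sex: str = "M",
    age: float = 35.0,
    hematocrit: float = REFERENCE_HEMATOCRIT,
    liver: Optional[LiverScalars] = None,
) -> VirtualSubject:
    """Reference adult, allometrically rescaled to ``body_weight`` if needed.

    Volumes scale linearly with body weight; flows with weight^0.75.
    """
    scale_v = body_weight / REFERENCE_BODY_WEIGHT
    scale_q = scale_v ** 0.75
    co = REFERENCE_CARDIAC_OUTPUT * scale_q
    flows = {t: f * co for t, f in REFERENCE_FLOW_FRACTIONS.items()}
    volumes = {t: v * scale_v for t, v in REFERENCE_ORGAN_VOLUMES.items()}
    if liver is None:
        liver = LiverScalars(
            liver_mass=1650.0 * scale_v,
            hepatic_blood_flow=flows["liver"] + sum(
                flows[t] for t in SPLANCHNIC_TISSUES),
        )
    return VirtualSubject(
        id=subject_id,
        sex=sex,
        age=age,
        body_weight=body_weight,
        organ_volumes=volumes,
        blood_flows=flows,
        cardiac_output=co,
        blood_volume=REFERENCE_BLOOD_VOLUME * scale_v,
        hematocrit=hematocrit,
        liver=liver,
        cyp_phenotypes={"CYP2D6": "EM"},
    )
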