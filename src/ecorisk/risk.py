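"""Risk characterization: SSD input aggregation, predicted no-effect
concentrations, concentration-addition mixture decomposition, and risk
quotients.

A PNEC is a hazard benchmark divided by an uncertainty (assessment)
factor: HC5/10 in the probabilistic route, or the minimum chronic NOEC
divided by 100 in the conventional route. A risk quotient above 1
(measured environmental concentration / PNEC) flags ecological risk.
Mixture contributions follow concentration addition on a molar basis:
each component's toxic unit is its concentration divided by its own
EC50, and toxic units sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .datamodel import ChemicalSpec, ExposureRecord, ToxicityRecord

__all__ = [
    "MixtureComponent",
    "PnecResult",
    "RiskSummary",
    "aggregate_species_geomeans",
    "derive_pnec",
    "mixture_toxic_units",
    "risk_quotient",
]

PnecBasis = Literal["hc5_probabilistic", "min_noec_conventional"]


@dataclass(frozen=True)
class MixtureComponent:
    """One degradation product in a concentration-addition budget."""

    chem: ChemicalSpec
    ec50_molar: float  # nmol/L

    def __post_init__(self) -> None:
        if not self.ec50_molar > 0:
            raise ValueError("ec50_molar must be positive")

    @property
    def molecules_per_parent(self) -> int:
        return self.chem.molecules_per_parent


@dataclass(frozen=True)
class PnecResult:
    """A predicted no-effect concentration with its provenance."""

    basis: PnecBasis
    input_value: float  # µg/L
    uncertainty_factor: float
    pnec: float  # µg/L


@dataclass(frozen=True)
class RiskSummary:
    """Risk quotient of one analyte against one PNEC."""

    analyte: str
    mec: float  # µg/L, measured environmental concentration
    pnec: PnecResult
    risk_quotient: float
    exceeds: bool


def aggregate_species_geomeans(
    records: Sequence[ToxicityRecord],
    exposure_class: Optional[str] = "acute",
    endpoints: Sequence[str] = ("EC50", "LC50"),
) -> list[tuple[str, float]]:
    """One value per species: the geometric mean of its comparable
    toxicity values (singletons pass through).

    Records are filtered to ``exposure_class`` and ``endpoints`` first;
    species order follows first appearance.
    """
    by_species: dict[str, list[float]] = {}
    for r in records:
        if exposure_class is not None and r.exposure_class != exposure_class:
            continue
        if r.endpoint not in endpoints:
            continue
        by_species.setdefault(r.species, []).append(r.value)
    if not by_species:
        raise ValueError("no records match the requested class/endpoints")
    return [
        (sp, float(np.exp(np.mean(np.log(vals)))))
        for sp, vals in by_species.items()
    ]


def derive_pnec(value: float, uf: float, basis: PnecBasis) -> PnecResult:
    """PNEC = hazard value / uncertainty factor, with provenance."""
    if not value > 0:
        raise ValueError("input value must be positive")
    if uf < 1:
        raise ValueError("uncertainty factor must be >= 1")
    return PnecResult(basis=basis, input_value=value, uncertainty_factor=uf,
                      pnec=value / uf)


def mixture_toxic_units(
    parent_conc_molar: float,
    parent_ec50_molar: float,
    components: Sequence[MixtureComponent],
) -> dict:
    """Concentration-addition decomposition of a parent compound into its
    degradation products.

    At a parent concentration ``C`` (nM), full breakdown releases
    ``molecules_per_parent × C`` of each component, so component i
    contributes ``TU_i = m_i·C / EC50_i`` toxic units while the parent
    itself represents ``TU = C / EC50_parent``. ``fractions`` are the
    component shares of the parent's toxic unit, evaluated at the parent
    EC50 — concentration-independent because every TU is linear in C.
    """
    if parent_ec50_molar <= 0:
        raise ValueError("parent EC50 must be positive")
    if parent_conc_molar < 0:
        raise ValueError("parent concentration must be >= 0")
    parent_tu = parent_conc_molar / parent_ec50_molar
    component_tus = {
        c.chem.name: parent_conc_molar * c.molecules_per_parent / c.ec50_molar
        for c in components
    }
    fractions = {
        c.chem.name: parent_ec50_molar * c.molecules_per_parent / c.ec50_molar
        for c in components
    }
    return {
        "parent_tu": parent_tu,
        "component_tus": component_tus,
        "total": sum(component_tus.values()),
        "fractions": fractions,
    }


def risk_quotient(mec: float, pnec: PnecResult, analyte: str = "") -> RiskSummary:
    """RQ = MEC / PNEC; ``exceeds`` iff RQ > 1."""
    if mec < 0:
        raise ValueError("measured concentration must be >= 0")
    if not pnec.pnec > 0:
        raise ValueError("PNEC must be positive")
    rq = mec / pnec.pnec
    return RiskSummary(analyte=analyte, mec=mec, pnec=pnec,
                       risk_quotient=rq, exceeds=rq > 1)
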