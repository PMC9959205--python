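"""Domain types for toxicity data and assay datasets.

The containers here mirror how marine ecotoxicity studies report their
results: per-species toxicity values (EC50/LC50/NOEC/...) feeding a species
sensitivity distribution, and per-treatment bioassay tables (algal growth
inhibition or crustacean immobilization) feeding dose-response fits.

All concentrations are held internally in µg/L. Non-detect measurements are
represented as ``None`` alongside the assay's detection limit; substitution
policy (e.g. using the detection limit as a working value) belongs to the
consumers, never to the containers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

__all__ = [
    "TaxonGroup",
    "Endpoint",
    "ExposureClass",
    "AssayType",
    "ToxicityRecord",
    "GrowthObservation",
    "QuantalCount",
    "Treatment",
    "DoseResponseDataset",
    "ExposureRecord",
    "ChemicalSpec",
    "ValidationError",
]

TaxonGroup = Literal["algae", "crustacean", "fish"]
Endpoint = Literal["EC50", "LC50", "NOEC", "LOEC", "MATC"]
ExposureClass = Literal["acute", "chronic"]
AssayType = Literal["algal_growth", "immobilization"]

_TAXA = ("algae", "crustacean", "fish")
_ENDPOINTS = ("EC50", "LC50", "NOEC", "LOEC", "MATC")
_CLASSES = ("acute", "chronic")


class ValidationError(ValueError):
    """A record or dataset violates one of its declared invariants."""


@dataclass(frozen=True)
class ToxicityRecord:
    """One species x endpoint x duration toxicity value.

    ``value`` is the toxicity concentration in µg/L; ``ci_low``/``ci_high``
    are the reported 95% confidence bounds when available.
    """

    species: str
    taxon_group: TaxonGroup
    endpoint: Endpoint
    exposure_class: ExposureClass
    duration_hours: float
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.taxon_group not in _TAXA:
            raise ValidationError(f"unknown taxon_group {self.taxon_group!r}")
        if self.endpoint not in _ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.exposure_class not in _CLASSES:
            raise ValidationError(f"unknown exposure_class {self.exposure_class!r}")
        if not self.duration_hours > 0:
            raise ValidationError(f"duration_hours must be > 0, got {self.duration_hours}")
        if not self.value > 0:
            raise ValidationError(f"toxicity value must be > 0, got {self.value}")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValidationError(
                    f"confidence interval ({self.ci_low}, {self.ci_high}) "
                    f"does not bracket value {self.value}"
                )
            if self.ci_low <= 0:
                raise ValidationError("ci_low must be positive")


@dataclass(frozen=True)
class GrowthObservation:
    """Start/end cell densities of one replicate of a growth-inhibition test."""

    n_start: float  # cells/mL at 0 h
    n_end: float  # cells/mL at end of test
    duration_days: float = 3.0

    def __post_init__(self) -> None:
        if not (self.n_start > 0 and self.n_end > 0):
            raise ValidationError("cell densities must be positive")
        if not self.duration_days > 0:
            raise ValidationError("duration_days must be positive")


@dataclass(frozen=True)
class QuantalCount:
    """Pooled immobilization count of one treatment."""

    n_exposed: int
    n_immobile: int

    def __post_init__(self) -> None:
        if self.n_exposed < 1:
            raise ValidationError("n_exposed must be >= 1")
        if not 0 <= self.n_immobile <= self.n_exposed:
            raise ValidationError(
                f"n_immobile ({self.n_immobile}) must lie in [0, n_exposed={self.n_exposed}]"
            )

    @property
    def proportion(self) -> float:
        return self.n_immobile / self.n_exposed


@dataclass(frozen=True)
class Treatment:
    """One concentration level of a bioassay.

    ``measured_start`` / ``measured_end`` are analytically measured
    concentrations; ``None`` encodes a non-detect (below
    ``detection_limit``). ``rates`` optionally carries per-replicate
    specific growth rates directly (published tables often print only
    summaries from which replicates are reconstructed).
    """

    label: str
    nominal_conc: float
    detection_limit: float = 0.04
    measured_start: Optional[float] = None
    measured_end: Optional[float] = None
    measured_geomean: Optional[float] = None
    growth: tuple[GrowthObservation, ...] = ()
    rates: tuple[float, ...] = ()
    quantal: Optional[QuantalCount] = None
    is_control: bool = False
    is_solvent_control: bool = False

    def __post_init__(self) -> None:
        if self.nominal_conc < 0:
            raise ValidationError("nominal_conc must be >= 0")
        if not self.detection_limit > 0:
            raise ValidationError("detection_limit must be positive")
        for m in (self.measured_start, self.measured_end):
            if m is not None and m < 0:
                raise ValidationError("measured concentrations must be >= 0")
        object.__setattr__(self, "growth", tuple(self.growth))
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))

    def growth_rates(self) -> tuple[float, ...]:
        """Per-replicate specific growth rates (per day).

        Uses directly supplied rates when present, otherwise derives them
        from the start/end cell densities.
        """
        if self.rates:
            return self.rates
        return tuple(
            math.log(g.n_end / g.n_start) / g.duration_days for g in self.growth
        )

    def geomean_measured(self) -> Optional[float]:
        """Geometric mean of start/end measured concentrations.

        Returns ``None`` (a non-detect) when either measurement is below
        the detection limit, matching how end-of-test losses below the
        analytical limit are reported. A directly reported geometric mean
        (``measured_geomean``) takes precedence, since published means are
        computed from unrounded measurements.
        """
        if self.measured_geomean is not None:
            return self.measured_geomean
        if self.measured_start is None or self.measured_end is None:
            return None
        return math.sqrt(self.measured_start * self.measured_end)


@dataclass(frozen=True)
class DoseResponseDataset:
    """One bioassay: a set of treatments plus metadata.

    Invariants: at most one solvent control; at least 4 non-control
    treatments with strictly increasing nominal concentrations.
    """

    assay_type: AssayType
    organism: str
    duration_hours: float
    treatments: tuple[Treatment, ...]
    unit: str = "µg/L"
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if self.assay_type not in ("algal_growth", "immobilization"):
            raise ValidationError(f"unknown assay_type {self.assay_type!r}")
        n_sc = sum(t.is_solvent_control for t in self.treatments)
        if n_sc > 1:
            raise ValidationError("at most one solvent-control treatment per dataset")
        exposed = self.exposed_treatments()
        if len(exposed) < 4:
            raise ValidationError(
                f"need >= 4 non-control treatments, got {len(exposed)}"
            )
        concs = [t.nominal_conc for t in exposed]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValidationError(
                "non-control nominal concentrations must be strictly increasing"
            )

    def exposed_treatments(self) -> tuple[Treatment, ...]:
        return tuple(
            t for t in self.treatments if not (t.is_control or t.is_solvent_control)
        )

    @property
    def solvent_control(self) -> Optional[Treatment]:
        for t in self.treatments:
            if t.is_solvent_control:
                return t
        return None

    @property
    def control(self) -> Optional[Treatment]:
        for t in self.treatments:
            if t.is_control and not t.is_solvent_control:
                return t
        return None

    def reference_treatment(self) -> Treatment:
        """The reference for inhibition/significance: the solvent control
        when present (carrier-solvent exposure matches the treatments),
        otherwise the plain control."""
        ref = self.solvent_control or self.control
        if ref is None:
            raise ValidationError("dataset has no control or solvent control")
        return ref


@dataclass(frozen=True)
class ExposureRecord:
    """A measured environmental concentration of one analyte."""

    analyte: str
    location: str
    concentration: float  # µg/L

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")


@dataclass(frozen=True)
class ChemicalSpec:
    """Identity, molecular weight and stoichiometric multiplicity of a
    chemical within its parent compound."""

    name: str
    molecular_weight: float  # g/mol
    molecules_per_parent: int = 1

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValidationError("molecular_weight must be positive")
        if self.molecules_per_parent < 1:
            raise ValidationError("molecules_per_parent must be >= 1")


# The study chemicals: the polymeric dithiocarbamate antifoulant and its two
# degradation products (a parent molecule releases two dimethyldithiocarbamate
# units and one ethylenebisdithiocarbamate unit on hydrolysis).
POLYCARBAMATE = ChemicalSpec("polycarbamate", 581.56, 1)
NA_DMDC = ChemicalSpec("Na-DMDC", 143.21, 2)
NA2_EBDC = ChemicalSpec("2Na-EBDC", 256.34, 1)
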