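"""CSV readers/writers and packaged study fixtures.

Two tabular schemas are supported:

* **Toxicity records** — one row per species x endpoint value, columns
  ``species, taxon_group, endpoint, exposure_class, duration_hours,
  value_ugL, ci_low, ci_high[, source]``.
* **Assay datasets** — long format, one row per treatment x replicate,
  columns ``organism, assay_type, duration_hours, unit, label,
  nominal_conc, measured_start, measured_end, measured_geomean,
  detection_limit, is_control, is_solvent_control, replicate`` plus either
  ``n_start, n_end`` / ``rate`` (growth assays) or ``n_exposed,
  n_immobile`` (quantal assays).

Dialect: comma-separated, UTF-8, ``.`` decimal, header required. Empty
measured cells encode non-detects (below the row's detection limit);
readers never substitute a number for them. All concentrations are
normalized to µg/L on read (rows declaring ``mg/L`` are scaled by 1000,
with the original unit retained on the dataset).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .datamodel import (
    AssayType,
    DoseResponseDataset,
    ExposureRecord,
    GrowthObservation,
    QuantalCount,
    ToxicityRecord,
    Treatment,
    ValidationError,
)

__all__ = [
    "read_toxicity_records",
    "write_toxicity_records",
    "read_assay_dataset",
    "write_assay_dataset",
    "read_exposure_records",
    "load_packaged_fixture",
    "fixture_names",
    "fixture_path",
]

_TOX_REQUIRED = [
    "species",
    "taxon_group",
    "endpoint",
    "exposure_class",
    "duration_hours",
    "value_ugL",
    "ci_low",
    "ci_high",
]


class SchemaError(ValueError):
    """The file is missing required columns or mixes incompatible ones."""


def _opt(x) -> Optional[float]:
    """NaN/empty -> None, else float."""
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def read_toxicity_records(path: Union[str, Path]) -> list[ToxicityRecord]:
    """Read a toxicity-record CSV, validating every row.

    Malformed rows are reported with their (1-based, header-exclusive)
    row number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TOX_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ToxicityRecord(
                    species=str(row["species"]),
                    taxon_group=str(row["taxon_group"]),
                    endpoint=str(row["endpoint"]),
                    exposure_class=str(row["exposure_class"]),
                    duration_hours=float(row["duration_hours"]),
                    value=float(row["value_ugL"]),
                    ci_low=_opt(row["ci_low"]),
                    ci_high=_opt(row["ci_high"]),
                    source=str(row.get("source", "") or ""),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i + 1}: {exc}") from exc
    return records


def write_toxicity_records(
    records: Sequence[ToxicityRecord], path: Union[str, Path]
) -> None:
    rows = [
        {
            "species": r.species,
            "taxon_group": r.taxon_group,
            "endpoint": r.endpoint,
            "exposure_class": r.exposure_class,
            "duration_hours": r.duration_hours,
            "value_ugL": r.value,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TOX_REQUIRED + ["source"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# long-format assay datasets


def read_assay_dataset(
    path: Union[str, Path], assay_type: Optional[AssayType] = None
) -> DoseResponseDataset:
    """Read a long-format assay CSV into a :class:`DoseResponseDataset`."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("organism", "duration_hours", "label", "nominal_conc"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    units = set(df["unit"]) if "unit" in df.columns else {"µg/L"}
    if len(units) > 1:
        raise SchemaError(f"{path}: mixed units in one dataset: {sorted(units)}")
    unit = next(iter(units))
    scale = 1000.0 if unit in ("mg/L", "mg/l") else 1.0

    if assay_type is None:
        assay_type = "immobilization" if "n_exposed" in df.columns else "algal_growth"

    treatments = []
    for label, grp in df.groupby("label", sort=False):
        first = grp.iloc[0]
        kwargs = dict(
            label=str(label),
            nominal_conc=float(first["nominal_conc"]) * scale,
            detection_limit=float(first.get("detection_limit", 0.04)) * scale,
            measured_start=_scale(_opt(first.get("measured_start")), scale),
            measured_end=_scale(_opt(first.get("measured_end")), scale),
            measured_geomean=_scale(_opt(first.get("measured_geomean")), scale),
            is_control=bool(first.get("is_control", False)),
            is_solvent_control=bool(first.get("is_solvent_control", False)),
        )
        try:
            if assay_type == "immobilization":
                kwargs["quantal"] = QuantalCount(
                    int(grp["n_exposed"].sum()), int(grp["n_immobile"].sum())
                )
            elif "rate" in grp.columns and grp["rate"].notna().any():
                kwargs["rates"] = tuple(float(r) for r in grp["rate"].dropna())
            else:
                kwargs["growth"] = tuple(
                    GrowthObservation(
                        float(r["n_start"]),
                        float(r["n_end"]),
                        float(first["duration_hours"]) / 24.0,
                    )
                    for _, r in grp.iterrows()
                )
            treatments.append(Treatment(**kwargs))
        except (ValidationError, KeyError, ValueError) as exc:
            raise ValidationError(f"{path}: treatment {label!r}: {exc}") from exc

    if sum(t.is_solvent_control for t in treatments) > 1:
        raise ValidationError(f"{path}: duplicate solvent-control treatment")
    return DoseResponseDataset(
        assay_type=assay_type,
        organism=str(df.iloc[0]["organism"]),
        duration_hours=float(df.iloc[0]["duration_hours"]),
        treatments=tuple(treatments),
        unit=unit,
    )


def _scale(x: Optional[float], k: float) -> Optional[float]:
    return None if x is None else x * k


def write_assay_dataset(ds: DoseResponseDataset, path: Union[str, Path]) -> None:
    """Write a dataset in the long format accepted by
    :func:`read_assay_dataset`. Concentrations are written in µg/L
    regardless of the dataset's original reporting unit."""
    rows = []
    for t in ds.treatments:
        base = {
            "organism": ds.organism,
            "assay_type": ds.assay_type,
            "duration_hours": ds.duration_hours,
            "unit": "µg/L",
            "label": t.label,
            "nominal_conc": t.nominal_conc,
            "measured_start": t.measured_start,
            "measured_end": t.measured_end,
            "measured_geomean": t.measured_geomean,
            "detection_limit": t.detection_limit,
            "is_control": t.is_control,
            "is_solvent_control": t.is_solvent_control,
        }
        if ds.assay_type == "immobilization":
            rows.append(
                base
                | {
                    "replicate": 1,
                    "n_exposed": t.quantal.n_exposed,
                    "n_immobile": t.quantal.n_immobile,
                }
            )
        elif t.growth:
            for i, g in enumerate(t.growth, 1):
                rows.append(base | {"replicate": i, "n_start": g.n_start, "n_end": g.n_end})
        else:
            for i, r in enumerate(t.rates, 1):
                rows.append(base | {"replicate": i, "rate": r})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_exposure_records(path: Union[str, Path]) -> list[ExposureRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("analyte", "concentration_ugL"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return [
        ExposureRecord(
            str(r["analyte"]), str(r.get("location", "") or ""), float(r["concentration_ugL"])
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# packaged fixtures (machine-readable transcriptions of the study tables)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    p = resources.files("ecorisk.data") / f"{name}.csv"
    if not p.is_file():
        raise LookupError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    return Path(str(p))


def fixture_names() -> list[str]:
    return sorted(
        p.name[:-4]
        for p in resources.files("ecorisk.data").iterdir()
        if p.name.endswith(".csv")
    )


def _load_summary_assay(name: str, assay_type: AssayType, organism: str,
                        duration_hours: float) -> DoseResponseDataset:
    """Build a dataset from a per-treatment summary fixture.

    Growth fixtures print each treatment's rate as mean ± standard error
    of triplicates; replicates are reconstructed as the unique symmetric
    triple {m - s*sqrt(3), m, m + s*sqrt(3)} that restores both summary
    statistics exactly.
    """
    from .simulate import reconstruct_replicates_from_summary

    df = pd.read_csv(fixture_path(name), float_precision="round_trip")
    treatments = []
    for _, row in df.iterrows():
        kwargs = dict(
            label=str(row["label"]),
            nominal_conc=float(row["nominal_ugL"]),
            detection_limit=float(row["detection_limit_ugL"]),
            measured_start=_opt(row["measured_start_ugL"]),
            measured_end=_opt(row["measured_end_ugL"]),
            measured_geomean=_opt(row["geomean_ugL"]),
            is_control=bool(row["is_control"]),
            is_solvent_control=bool(row["is_solvent_control"]),
        )
        if assay_type == "algal_growth":
            kwargs["rates"] = reconstruct_replicates_from_summary(
                float(row["rate_mean"]), float(row["rate_se"])
            )
        else:
            kwargs["quantal"] = QuantalCount(int(row["n_exposed"]), int(row["n_immobile"]))
        treatments.append(Treatment(**kwargs))
    return DoseResponseDataset(
        assay_type=assay_type,
        organism=organism,
        duration_hours=duration_hours,
        treatments=tuple(treatments),
    )


_ASSAY_FIXTURES = {
    "table1_dunaliella": ("algal_growth", "Dunaliella tertiolecta", 72.0),
    "table1_skeletonema": ("algal_growth", "Skeletonema marinoi-dohrnii complex", 72.0),
    "table1_tetraselmis": ("algal_growth", "Tetraselmis tetrathele", 72.0),
    "table2_bluecrab": ("immobilization", "Japanese blue crab", 24.0),
    "table2_tigriopus": ("immobilization", "Tigriopus japonicus", 24.0),
    "table3_dmdc": ("algal_growth", "Skeletonema marinoi-dohrnii complex", 72.0),
    "table3_ebdc": ("algal_growth", "Skeletonema marinoi-dohrnii complex", 72.0),
}


def load_packaged_fixture(name: str):
    """Load a packaged fixture by name.

    Returns a :class:`DoseResponseDataset` (table1_*/table2_*/table3_*),
    a list of :class:`ToxicityRecord` (table4_*), a list of
    :class:`ExposureRecord` (exposure_*), or a :class:`pandas.DataFrame`
    (table5_reference). Contents are bit-identical across calls.
    """
    if name in _ASSAY_FIXTURES:
        return _load_summary_assay(name, *_ASSAY_FIXTURES[name])
    if name.startswith("table4"):
        return read_toxicity_records(fixture_path(name))
    if name.startswith("exposure"):
        return read_exposure_records(fixture_path(name))
    if name == "table5_reference":
        return pd.read_csv(fixture_path(name), float_precision="round_trip")
    raise LookupError(
        f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
    )
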