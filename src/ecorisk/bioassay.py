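"""Bioassay endpoint arithmetic.

Specific growth rate and percent inhibition for algal growth-inhibition
tests, geometric-mean exposure concentrations, back-calculation of the
parent antifoulant from its derivatized analyte, and mass/molar
conversion. Growth rates and inhibitions are computed per replicate and
summarized as mean ± standard error (SE = sd/sqrt(n)); the solvent
control is the reference when one exists.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .datamodel import ChemicalSpec, DoseResponseDataset, GrowthObservation

__all__ = [
    "specific_growth_rate",
    "percent_inhibition",
    "exposure_geomean",
    "pc_from_dmdc_methyl",
    "mass_to_molar",
    "molar_to_mass",
    "summarize_growth",
    "measured_to_nominal_ratios",
]

#: Slope of the analyte-to-parent regression: parent µg/L per µg/L of the
#: methylated dimethyldithiocarbamate analyte.
PC_PER_DMDC_METHYL = 0.89 / 0.41


def specific_growth_rate(obs: GrowthObservation) -> float:
    """Specific growth rate µ = ln(N_end/N_start) / duration, per day.

    Negative when the culture declined below its inoculum density.
    """
    if not (obs.n_start > 0 and obs.n_end > 0):
        raise ValueError("cell densities must be positive")
    return math.log(obs.n_end / obs.n_start) / obs.duration_days


def percent_inhibition(mu_control: float, mu_treatment: float) -> float:
    """Growth-rate inhibition I = (µ_c − µ_t)/µ_c × 100.

    Exceeds 100% exactly when the treated culture shrank (µ_t < 0).
    """
    if mu_control <= 0:
        raise ValueError("control growth rate must be positive")
    return (mu_control - mu_treatment) / mu_control * 100.0


def exposure_geomean(
    c_start: float, c_end: Optional[float], dl: float
) -> Optional[float]:
    """Geometric mean of start/end-of-test measured concentrations.

    ``c_end=None`` marks an end-of-test non-detect (< dl); the mean is
    then itself a non-detect and ``None`` is returned.
    """
    if c_start is None or c_start < 0 or (c_end is not None and c_end < 0):
        raise ValueError("concentrations must be non-negative")
    if not dl > 0:
        raise ValueError("detection limit must be positive")
    if c_end is None:
        return None
    return math.sqrt(c_start * c_end)


def pc_from_dmdc_methyl(d: float) -> float:
    """Parent concentration back-calculated from the DMDC-methyl analyte:
    p = d × 0.89/0.41."""
    if d < 0:
        raise ValueError("analyte concentration must be non-negative")
    return d * PC_PER_DMDC_METHYL


def mass_to_molar(c_ugL: float, chem: ChemicalSpec) -> float:
    """µg/L -> nmol/L: nM = c / MW × 1000."""
    if c_ugL < 0:
        raise ValueError("concentration must be non-negative")
    return c_ugL / chem.molecular_weight * 1000.0


def molar_to_mass(c_nM: float, chem: ChemicalSpec) -> float:
    """nmol/L -> µg/L (inverse of :func:`mass_to_molar`)."""
    if c_nM < 0:
        raise ValueError("concentration must be non-negative")
    return c_nM * chem.molecular_weight / 1000.0


def summarize_growth(ds: DoseResponseDataset) -> "list[dict]":
    """Per-treatment growth-rate and inhibition summaries.

    Returns one dict per treatment with replicate-level mean ± SE of the
    specific growth rate and of percent inhibition relative to the mean
    rate of the reference (solvent control when present).
    """
    ref_rates = np.asarray(ds.reference_treatment().growth_rates())
    mu_ref = float(ref_rates.mean())
    out = []
    for t in ds.treatments:
        rates = np.asarray(t.growth_rates(), dtype=float)
        inh = np.array([percent_inhibition(mu_ref, r) for r in rates])
        n = len(rates)
        out.append(
            {
                "label": t.label,
                "n": n,
                "rate_mean": float(rates.mean()),
                "rate_se": float(rates.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                "inhibition_mean": float(inh.mean()),
                "inhibition_se": float(inh.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
            }
        )
    return out


def measured_to_nominal_ratios(ds: DoseResponseDataset) -> dict:
    """Mean ± SE of measured/nominal concentration ratios (percent),
    computed separately from the 0 h measurement, the end-of-test
    measurement, and their geometric mean. Non-detect measurements and
    controls are skipped. All three bases are exposed; none is singled
    out as canonical."""
    out = {}
    for key, get in (
        ("start", lambda t: t.measured_start),
        ("end", lambda t: t.measured_end),
        ("geomean", lambda t: t.geomean_measured()),
    ):
        ratios = [
            get(t) / t.nominal_conc * 100.0
            for t in ds.exposed_treatments()
            if get(t) is not None and t.nominal_conc > 0
        ]
        if ratios:
            r = np.asarray(ratios)
            out[key] = {
                "mean": float(r.mean()),
                "se": float(r.std(ddof=1) / math.sqrt(len(r))) if len(r) > 1 else 0.0,
                "n": len(r),
            }
    return out
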