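"""Synthetic-data generators with the statistical structure the analysis
assumes.

Three generators mirror the designs the pipeline consumes: inter-species
toxicity samples drawn from a candidate SSD family, algal
growth-inhibition assays with a log-logistic concentration-response and
multiplicative triplicate noise, and binomial immobilization assays. All
generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    DoseResponseDataset,
    GrowthObservation,
    QuantalCount,
    Treatment,
)
from .ssd import DISTRIBUTIONS, CandidateDistribution

__all__ = [
    "simulate_ssd_values",
    "simulate_algal_assay",
    "simulate_quantal_assay",
    "reconstruct_replicates_from_summary",
]

#: Default geometric concentration series (µg/L), mimicking the dynamic
#: range of a marine algal inhibition test on a potent antifoulant.
DEFAULT_CONCENTRATIONS = (0.3, 0.45, 0.65, 2.3, 4.7)


def simulate_ssd_values(
    dist: "str | CandidateDistribution",
    params: Sequence[float],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` independent toxicity values from a fitted SSD family.

    This is the parametric-bootstrap building block: reproducible per
    seed, with parameters in the family's public parameterization.
    """
    d = DISTRIBUTIONS[dist] if isinstance(dist, str) else dist
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    try:
        out = d.rvs(tuple(params), n, rng)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid parameters for {d.name}: {params}") from exc
    if not np.all(np.isfinite(out)) or np.any(out <= 0):
        raise ValueError(f"invalid parameters for {d.name}: {params}")
    return out


def simulate_algal_assay(
    ec50: float,
    slope: float = 4.0,
    mu_control: float = 1.45,
    cv: float = 0.05,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    n_reps: int = 3,
    seed: int = 0,
    duration_days: float = 3.0,
    n_start: float = 1e5,
    measured_start_fraction: Optional[float] = None,
    measured_end_fraction: Optional[float] = None,
) -> DoseResponseDataset:
    """Simulate a triplicate algal growth-inhibition test.

    The true rate follows a log-logistic curve whose lower asymptote sits
    1.6/d below the control rate — deep enough that high doses drive the
    rate negative (cultures shrinking), as observed in practice. Each
    replicate's final density is ``n_start * exp(duration * µ(c)) * ε``
    with multiplicative log-normal noise ε (sdlog = cv), keeping
    densities positive and the coefficient of variation roughly constant.
    A control and a solvent control grow at ``mu_control``. Measured
    concentrations, when requested, are the nominal value times a fixed
    loss fraction (no decay kinetics are modelled).
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    lower = mu_control - 1.6
    if mu_control / 2 <= lower:
        raise ValueError("mu_control too large for the fixed asymptote depth")
    # place the inflection so that ``ec50`` is exactly the concentration
    # halving the control rate (the endpoint the fit reports), not the
    # curve's own midpoint — the two differ when the lower asymptote is
    # not zero
    span = mu_control - lower
    infl = ec50 / (span / (mu_control / 2 - lower) - 1) ** (1 / slope)

    def true_mu(c):
        return lower + span / (1 + (c / infl) ** slope)

    def make_growth(mu):
        obs = []
        for _ in range(n_reps):
            eps = math.exp(rng.normal(0.0, cv)) if cv > 0 else 1.0
            obs.append(
                GrowthObservation(
                    n_start, n_start * math.exp(duration_days * mu) * eps, duration_days
                )
            )
        return tuple(obs)

    def measured(c, frac):
        return None if frac is None else c * frac

    treatments = [
        Treatment(label="Control", nominal_conc=0.0, is_control=True,
                  growth=make_growth(mu_control)),
        Treatment(label="SC", nominal_conc=0.0, is_solvent_control=True,
                  growth=make_growth(mu_control)),
    ]
    for c in concentrations:
        treatments.append(
            Treatment(
                label=f"{c:g}", nominal_conc=float(c),
                measured_start=measured(c, measured_start_fraction),
                measured_end=measured(c, measured_end_fraction),
                growth=make_growth(true_mu(c)),
            )
        )
    return DoseResponseDataset(
        assay_type="algal_growth",
        organism="synthetic alga",
        duration_hours=duration_days * 24,
        treatments=tuple(treatments),
    )


def simulate_quantal_assay(
    ec50: float,
    slope: float = 2.0,
    background: float = 0.0,
    concentrations: Sequence[float] = (0.9, 2.2, 4.0, 6.5, 13.3),
    n_exposed: int = 20,
    seed: int = 0,
    duration_hours: float = 24.0,
) -> DoseResponseDataset:
    """Simulate a crustacean immobilization test with binomial counts at
    ``p(c) = background + (1 − background)·expit(slope·ln(c/ec50))``."""
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if not 0 <= background < 1:
        raise ValueError("background must be in [0, 1)")
    if n_exposed < 1:
        raise ValueError("n_exposed must be >= 1")
    rng = np.random.default_rng(seed)

    def p(c):
        return background + (1 - background) / (1 + (c / ec50) ** (-slope))

    treatments = [
        Treatment(label="Control", nominal_conc=0.0, detection_limit=0.2,
                  is_control=True,
                  quantal=QuantalCount(n_exposed, int(rng.binomial(n_exposed, background)))),
        Treatment(label="SC", nominal_conc=0.0, detection_limit=0.2,
                  is_solvent_control=True,
                  quantal=QuantalCount(n_exposed, int(rng.binomial(n_exposed, background)))),
    ]
    for c in concentrations:
        treatments.append(
            Treatment(
                label=f"{c:g}", nominal_conc=float(c), detection_limit=0.2,
                quantal=QuantalCount(n_exposed, int(rng.binomial(n_exposed, p(c)))),
            )
        )
    return DoseResponseDataset(
        assay_type="immobilization",
        organism="synthetic crustacean",
        duration_hours=duration_hours,
        treatments=tuple(treatments),
    )


def reconstruct_replicates_from_summary(
    mean: float, se: float, n: int = 3
) -> tuple[float, float, float]:
    """The symmetric triple {m − s√3, m, m + s√3} whose sample mean is
    ``mean`` and whose standard error (sd/√3) is ``se`` exactly.

    Published assay tables print only mean ± SE of triplicates; this
    reconstruction restores a replicate set consistent with both
    statistics (unique up to permutation among symmetric triples).
    Only n = 3 is supported.
    """
    if n != 3:
        raise ValueError("reconstruction is defined for triplicates (n=3) only")
    if se < 0:
        raise ValueError("se must be >= 0")
    d = se * math.sqrt(3.0)
    return (mean - d, mean, mean + d)
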