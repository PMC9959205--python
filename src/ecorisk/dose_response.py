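"""Dose-response estimation: EC50/LC50 fits and NOEC/LOEC determination.

Continuous (algal growth rate) data are fit with a log-logistic curve on
per-replicate specific growth rates,

    µ(c) = lower + (upper − lower) / (1 + (c/e)^b),

with the lower asymptote fixed at 0 by default (growth fully suppressed
at high dose; observed negative rates then act as residuals below the
floor). The reported EC50 is the concentration at which the predicted
rate equals half the solvent-control mean rate — an *absolute* 50%
effect level, not the curve's inflection — with a 95% CI by the delta
method on ln(EC50).

Quantal (immobilization) data are fit by binomial maximum likelihood
with the logit of the response proportion linear in ln(concentration);
the EC50 is the concentration at 50% response, optionally after Abbott
correction for background response.

NOEC/LOEC come from Dunnett's many-to-one comparisons of each treatment
against the solvent control at family-wise level alpha (two-sided).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .datamodel import DoseResponseDataset, Treatment, ValidationError

__all__ = [
    "DoseResponseFit",
    "NoecResult",
    "fit_continuous_ll3",
    "fit_quantal_ll2",
    "dunnett_noec_loec",
    "dunnett_critical_value",
]

ConcentrationBasis = Literal["nominal", "measured_geomean"]


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted dose-response curve and its EC50."""

    model: Literal["loglogistic_continuous", "loglogistic_quantal"]
    ec50: float
    ec50_ci: tuple[float, float]
    slope: float
    upper_asymptote: Optional[float]
    lower_asymptote: Optional[float]
    converged: bool
    n_treatments: int
    concentration_basis: ConcentrationBasis
    params: tuple = ()
    reference_response: Optional[float] = None
    messages: tuple[str, ...] = ()


def _basis_concentration(t: Treatment, basis: ConcentrationBasis) -> float:
    """Concentration of one treatment under the chosen basis.

    Under ``measured_geomean``, a non-detect geometric mean falls back to
    the detection limit (with a warning): the exposure was somewhere
    below it, and the detection limit is the least-biased usable bound.
    """
    if basis == "nominal":
        return t.nominal_conc
    g = t.geomean_measured()
    if g is None:
        warnings.warn(
            f"treatment {t.label!r}: non-detect measured concentration; "
            f"using detection limit {t.detection_limit} µg/L",
            stacklevel=3,
        )
        return t.detection_limit
    return g


def _ll4(c, lower, upper, log_e, b):
    with np.errstate(over="ignore"):
        return lower + (upper - lower) * special.expit(b * (log_e - np.log(c)))


def fit_continuous_ll3(
    dataset: DoseResponseDataset,
    basis: ConcentrationBasis = "measured_geomean",
    lower_free: bool = False,
    effect_fraction: float = 0.5,
) -> DoseResponseFit:
    """Log-logistic fit of per-replicate growth rates vs concentration.

    Least-squares (Gaussian ML) on all replicate rates of non-control
    treatments; controls never enter the curve. The EC_x is the
    concentration where the predicted rate equals
    ``(1 - effect_fraction)`` of the solvent-control mean rate
    (``effect_fraction=0.5`` -> EC50).
    """
    if dataset.assay_type != "algal_growth":
        raise ValidationError("continuous fit requires an algal_growth dataset")
    exposed = dataset.exposed_treatments()
    if len(exposed) < 4:
        raise ValidationError("need >= 4 non-control treatments")
    mu_ref = float(np.mean(dataset.reference_treatment().growth_rates()))
    concs, rates = [], []
    for t in exposed:
        c = _basis_concentration(t, basis)
        for r in t.growth_rates():
            concs.append(c)
            rates.append(r)
    c_arr, y = np.array(concs), np.array(rates)
    if np.any(c_arr <= 0):
        raise ValidationError("non-control treatments must have positive concentrations")

    target = (1.0 - effect_fraction) * mu_ref
    msgs: list[str] = []

    # initialize e at the concentration bracketing the target effect
    mean_by_c = {c: np.mean([yy for cc, yy in zip(c_arr, y) if cc == c])
                 for c in np.unique(c_arr)}
    cs_sorted = sorted(mean_by_c)
    e0 = math.sqrt(cs_sorted[0] * cs_sorted[-1])
    for lo_c, hi_c in zip(cs_sorted, cs_sorted[1:]):
        if (mean_by_c[lo_c] - target) * (mean_by_c[hi_c] - target) <= 0:
            e0 = math.sqrt(lo_c * hi_c)
            break

    if lower_free:
        def unpack(p):
            return p[0], p[1], p[2], p[3]
        p0s = [[min(y.min(), 0.0), mu_ref, math.log(e0), b0] for b0 in (0.5, 1, 2, 4, 8)]
    else:
        def unpack(p):
            return 0.0, p[0], p[1], p[2]
        p0s = [[mu_ref, math.log(e0), b0] for b0 in (0.5, 1, 2, 4, 8)]

    def ssq(p):
        lower, upper, log_e, b = unpack(p)
        return float(np.sum((y - _ll4(c_arr, lower, upper, log_e, b)) ** 2))

    best = None
    for p0 in p0s:
        res = optimize.minimize(
            ssq, p0, method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-12, "fatol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    lower, upper, log_e, b = unpack(best.x)
    converged = bool(best.success or best.fun < np.var(y) * len(y))

    # delta-method CI on ln EC50 via the least-squares covariance
    ec50, ci = _continuous_ec50_ci(
        c_arr, y, np.asarray(best.x, dtype=float), unpack, target, msgs
    )
    if ec50 is not None and not (c_arr.min() <= ec50 <= c_arr.max()):
        msgs.append("EC50 outside the tested concentration range (extrapolation)")
        warnings.warn(msgs[-1], stacklevel=2)
    return DoseResponseFit(
        model="loglogistic_continuous",
        ec50=float("nan") if ec50 is None else ec50,
        ec50_ci=ci,
        slope=float(b),
        upper_asymptote=float(upper),
        lower_asymptote=float(lower),
        converged=converged,
        n_treatments=len(exposed),
        concentration_basis=basis,
        params=tuple(float(v) for v in best.x),
        reference_response=mu_ref,
        messages=tuple(msgs),
    )


def _solve_ec(theta, unpack, target):
    lower, upper, log_e, b = unpack(theta)
    span = (upper - lower)
    if span <= 0 or not (min(lower, upper) < target < max(lower, upper)):
        return None
    # closed form: target = lower + span*expit(b*(log_e - ln c))
    frac = (target - lower) / span
    return log_e - special.logit(frac) / b


def _continuous_ec50_ci(c_arr, y, theta, unpack, target, msgs):
    log_ec = _solve_ec(theta, unpack, target)
    if log_ec is None:
        msgs.append("fitted curve does not cross the 50% effect level")
        return None, (float("nan"), float("nan"))
    ec50 = math.exp(log_ec)
    p = len(theta)
    # numeric Jacobian of the mean function and of ln EC50
    J = np.empty((len(c_arr), p))
    g = np.empty(p)
    f0 = _ll4(c_arr, *unpack(theta))
    for j in range(p):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        J[:, j] = (_ll4(c_arr, *unpack(tp)) - f0) / h
        le = _solve_ec(tp, unpack, target)
        g[j] = ((le - log_ec) / h) if le is not None else 0.0
    dof = len(y) - p
    if dof <= 0:
        return ec50, (float("nan"), float("nan"))
    rss = float(np.sum((y - f0) ** 2))
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se = math.sqrt(max(float(g @ cov @ g), 0.0))
    except np.linalg.LinAlgError:
        msgs.append("singular design: no CI available")
        return ec50, (float("nan"), float("nan"))
    z = stats.norm.ppf(0.975)
    if z * se > 300:  # curve so steep/ill-conditioned the CI is unbounded
        msgs.append("EC50 CI unbounded (ill-conditioned curvature)")
        return ec50, (0.0, float("inf"))
    return ec50, (ec50 * math.exp(-z * se), ec50 * math.exp(z * se))


def fit_quantal_ll2(
    dataset: DoseResponseDataset,
    basis: ConcentrationBasis = "measured_geomean",
    abbott: bool = False,
    include_solvent_control: bool = False,
) -> DoseResponseFit:
    """Binomial log-logistic fit of immobilization counts.

    The logit of the response proportion is linear in ln(concentration):
    ``p(c) = expit(b (ln c − ln e))``; with ``abbott=True`` a background
    response estimated from the pooled controls is added,
    ``p(c) = p0 + (1 − p0)·expit(...)``, and the EC50 refers to the
    control-corrected response.

    ``include_solvent_control`` adds the solvent-control group as a data
    point at its own (measured) concentration instead of excluding it —
    usable when the carrier blank contained a quantifiable residue.
    """
    if dataset.assay_type != "immobilization":
        raise ValidationError("quantal fit requires an immobilization dataset")
    pts = []
    for t in dataset.exposed_treatments():
        pts.append((_basis_concentration(t, basis), t.quantal.n_exposed, t.quantal.n_immobile))
    if include_solvent_control and dataset.solvent_control is not None:
        sc = dataset.solvent_control
        g = sc.geomean_measured()
        if g is not None and g > 0:
            pts.insert(0, (g, sc.quantal.n_exposed, sc.quantal.n_immobile))
    conc = np.array([p[0] for p in pts])
    n = np.array([p[1] for p in pts], dtype=float)
    k = np.array([p[2] for p in pts], dtype=float)

    background = 0.0
    if abbott:
        ctrl = [t for t in dataset.treatments if t.is_control or t.is_solvent_control]
        if ctrl:
            background = sum(t.quantal.n_immobile for t in ctrl) / sum(
                t.quantal.n_exposed for t in ctrl
            )

    if np.all(k == 0) or np.all(k == n):
        return DoseResponseFit(
            model="loglogistic_quantal", ec50=float("nan"),
            ec50_ci=(float("nan"), float("nan")), slope=float("nan"),
            upper_asymptote=None, lower_asymptote=None, converged=False,
            n_treatments=len(pts), concentration_basis=basis,
            messages=("all-zero or all-full response: EC50 not identifiable",),
        )

    lc = np.log(conc)

    def nll(p):
        b, log_e = p
        pr = special.expit(b * (lc - log_e))
        pr = background + (1 - background) * pr
        pr = np.clip(pr, 1e-12, 1 - 1e-12)
        return -float(np.sum(k * np.log(pr) + (n - k) * np.log(1 - pr)))

    e0 = float(np.exp(np.interp(0.5, k / n, lc))) if np.any(k / n >= 0.5) else float(conc[-1])
    best = None
    for b0 in (0.5, 1, 2, 4, 8):
        res = optimize.minimize(
            nll, [b0, math.log(e0)], method="Nelder-Mead",
            options={"maxiter": 10000, "xatol": 1e-12, "fatol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    b, log_e = best.x
    # observed-information CI on ln EC50
    H = _numeric_hessian(nll, best.x)
    ci = (float("nan"), float("nan"))
    se = float("nan")
    try:
        cov = np.linalg.inv(H)
        if cov[1, 1] > 0:
            se = math.sqrt(cov[1, 1])
            z = stats.norm.ppf(0.975)
            ci = (math.exp(log_e - z * se), math.exp(log_e + z * se))
    except np.linalg.LinAlgError:
        pass
    return DoseResponseFit(
        model="loglogistic_quantal",
        ec50=float(math.exp(log_e)),
        ec50_ci=ci,
        slope=float(b),
        upper_asymptote=None,
        lower_asymptote=None,
        converged=bool(np.isfinite(best.fun)),
        n_treatments=len(pts),
        concentration_basis=basis,
        params=(float(b), float(log_e), float(background)),
    )


def _numeric_hessian(f, x, rel=1e-5):
    x = np.asarray(x, dtype=float)
    p = len(x)
    H = np.empty((p, p))
    h = rel * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons


@dataclass(frozen=True)
class NoecResult:
    """NOEC/LOEC from many-to-one comparisons against the solvent control.

    ``noec_is_bound`` marks the "no significant effect anywhere" case,
    where the NOEC can only be stated as ">= highest tested".
    """

    noec: float
    loec: Optional[float]
    alpha: float
    noec_is_bound: bool
    per_treatment: tuple[dict, ...]

    def __str__(self) -> str:
        noec = f">= {self.noec:g}" if self.noec_is_bound else f"{self.noec:g}"
        loec = "none detected" if self.loec is None else f"{self.loec:g}"
        return f"NOEC {noec} µg/L, LOEC {loec} µg/L (alpha={self.alpha})"


def dunnett_noec_loec(
    dataset: DoseResponseDataset,
    alpha: float = 0.05,
    basis: ConcentrationBasis = "measured_geomean",
    rng: Optional[np.random.Generator] = None,
) -> NoecResult:
    """Dunnett's procedure on per-replicate growth rates.

    Two-sided comparisons of each treatment mean against the
    solvent-control mean with pooled within-group variance and the
    equal-correlation multivariate-t adjustment; family-wise level
    ``alpha``. The LOEC is the lowest concentration whose comparison is
    significant; the NOEC is the highest tested concentration below the
    LOEC (or the highest tested concentration when nothing is
    significant). Unbalanced replication is handled through the
    per-group sample sizes in the correlation structure.
    """
    ref = dataset.reference_treatment()
    ref_rates = np.asarray(ref.growth_rates(), dtype=float)
    exposed = dataset.exposed_treatments()
    groups = [np.asarray(t.growth_rates(), dtype=float) for t in exposed]
    if len(ref_rates) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 replicates per treatment for Dunnett's test")
    pooled = np.concatenate([ref_rates - ref_rates.mean()]
                            + [g - g.mean() for g in groups])
    if np.allclose(pooled, 0):
        raise ValidationError("zero pooled variance: comparisons are degenerate")
    with warnings.catch_warnings():
        # replicate groups reconstructed from summaries can have zero
        # within-group variance; the pooled estimate remains valid
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.dunnett(
            *groups, control=ref_rates, alternative="two-sided",
            rng=rng if rng is not None else np.random.default_rng(0),
        )
    concs = [_basis_concentration(t, basis) for t in exposed]
    per = tuple(
        {
            "label": t.label,
            "concentration": c,
            "statistic": float(s),
            "p_adjusted": float(p),
            "significant": bool(p < alpha),
        }
        for t, c, s, p in zip(exposed, concs, res.statistic, res.pvalue)
    )
    sig_concs = [row["concentration"] for row in per if row["significant"]]
    if not sig_concs:
        return NoecResult(
            noec=max(concs), loec=None, alpha=alpha, noec_is_bound=True,
            per_treatment=per,
        )
    loec = min(sig_concs)
    below = [c for c in concs if c < loec]
    # no tested concentration below the LOEC: the NOEC is unresolved
    # below the lowest treatment; report that concentration as an upper bound
    noec = max(below) if below else float("nan")
    return NoecResult(
        noec=noec, loec=loec, alpha=alpha, noec_is_bound=False, per_treatment=per
    )


def dunnett_critical_value(
    n_per_group: Sequence[int],
    n_control: int,
    alpha: float = 0.05,
    n_nodes: int = 64,
) -> float:
    """Two-sided equicoordinate critical value of Dunnett's statistic.

    Computes P(max_i |T_i| <= c) = 1 - alpha by quadrature over the
    factor-analytic representation T_i = (sqrt(1-λ_i²) Z_i + λ_i Z_0)/S
    with λ_i = sqrt(n_i/(n_i+n_0)) and S² the pooled variance estimate
    (chi²_ν/ν). For a single comparison this reduces to the two-sided
    Student-t critical value.
    """
    ns = np.asarray(n_per_group, dtype=float)
    nu = float(ns.sum() + n_control - len(ns) - 1)
    lam = np.sqrt(ns / (ns + n_control))
    # quadrature nodes: s over the chi_nu/sqrt(nu) distribution via its
    # quantile transform, z0 over the standard normal
    us, wu = np.polynomial.legendre.leggauss(n_nodes)
    us = 0.5 * (us + 1)
    wu = 0.5 * wu
    s_nodes = np.sqrt(stats.chi2.ppf(us, nu) / nu)
    z_nodes, wz = np.polynomial.legendre.leggauss(2 * n_nodes)
    z_nodes = 8.0 * z_nodes
    wz = 8.0 * wz * stats.norm.pdf(z_nodes)

    sqrt1m = np.sqrt(1 - lam**2)

    def prob(c):
        # P over grid: for each s, z0: prod_i [Phi((c s - lam z0)/sqrt) - Phi((-c s - lam z0)/sqrt)]
        cs = c * s_nodes[:, None, None]  # (s, 1, 1)
        z0 = z_nodes[None, :, None]  # (1, z, 1)
        upper = (cs - lam[None, None, :] * z0) / sqrt1m[None, None, :]
        lower = (-cs - lam[None, None, :] * z0) / sqrt1m[None, None, :]
        inner = np.prod(stats.norm.cdf(upper) - stats.norm.cdf(lower), axis=2)
        return float(wu @ inner @ wz)

    return optimize.brentq(lambda c: prob(c) - (1 - alpha), 0.5, 15.0, xtol=1e-10)
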