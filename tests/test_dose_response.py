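"""Dose-response fits (continuous + quantal) and Dunnett NOEC/LOEC."""

import math

import numpy as np
import pytest
from scipy import stats

from ecorisk import (
    DoseResponseDataset,
    QuantalCount,
    Treatment,
    ValidationError,
    dunnett_critical_value,
    dunnett_noec_loec,
    fit_continuous_ll3,
    fit_quantal_ll2,
    load_packaged_fixture,
    simulate_algal_assay,
    simulate_quantal_assay,
)


# --- continuous fits --------------------------------------------------------


def test_noiseless_synthetic_recovery_is_exact():
    ds = simulate_algal_assay(ec50=5.0, slope=2.0, mu_control=1.5, cv=0.0,
                              concentrations=(1.0, 2.5, 5.0, 10.0, 25.0), seed=0)
    fit = fit_continuous_ll3(ds, basis="nominal", lower_free=True)
    assert fit.ec50 == pytest.approx(5.0, rel=1e-6)
    assert fit.slope == pytest.approx(2.0, rel=1e-4)


def test_continuous_scale_equivariance():
    k = 4.2
    a = simulate_algal_assay(ec50=5.0, cv=0.03, seed=1,
                             concentrations=(1.0, 2.5, 5.0, 10.0, 25.0))
    b = simulate_algal_assay(ec50=5.0 * k, cv=0.03, seed=1,
                             concentrations=tuple(k * c for c in (1.0, 2.5, 5.0, 10.0, 25.0)))
    fa = fit_continuous_ll3(a, basis="nominal")
    fb = fit_continuous_ll3(b, basis="nominal")
    assert fb.ec50 == pytest.approx(k * fa.ec50, rel=1e-6)


def test_published_algal_ec50s_inside_printed_cis():
    expected = {
        "table1_skeletonema": (0.63, 0.82),
        "table1_dunaliella": (2.5, 3.5),
        "table1_tetraselmis": (10, 14),
    }
    for name, (lo, hi) in expected.items():
        fit = fit_continuous_ll3(load_packaged_fixture(name))
        assert lo < fit.ec50 < hi, name
        assert fit.converged


def test_extrapolation_flagged_when_curve_not_bracketed():
    ds = simulate_algal_assay(ec50=50.0, slope=2.0, cv=0.0,
                              concentrations=(0.5, 1.0, 2.0, 4.0, 8.0), seed=0)
    with pytest.warns(UserWarning, match="extrapolation"):
        fit = fit_continuous_ll3(ds, basis="nominal", lower_free=True)
    assert any("extrapolation" in m for m in fit.messages)


def test_continuous_fit_requires_algal_dataset(tigriopus):
    with pytest.raises(ValidationError):
        fit_continuous_ll3(tigriopus)


def test_ec50_recovery_under_replicate_noise():
    """Median relative EC50 error stays below 10% for triplicate assays
    with 5% multiplicative noise."""
    errors = []
    for i in range(500):
        ds = simulate_algal_assay(ec50=0.72, slope=4.0, mu_control=1.53, cv=0.05,
                                  concentrations=(0.29, 0.45, 0.65, 2.34, 4.66),
                                  seed=20_000 + i)
        fit = fit_continuous_ll3(ds, basis="nominal")
        errors.append(abs(fit.ec50 - 0.72) / 0.72)
    assert np.median(errors) < 0.10


# --- quantal fits -----------------------------------------------------------


def test_quantal_self_consistency_at_large_n():
    ds = simulate_quantal_assay(ec50=2.0, slope=2.5, background=0.0,
                                n_exposed=10_000, seed=4)
    fit = fit_quantal_ll2(ds, basis="nominal")
    assert fit.ec50 == pytest.approx(2.0, rel=0.02)
    assert fit.slope == pytest.approx(2.5, rel=0.1)


def test_quantal_scale_equivariance():
    a = simulate_quantal_assay(ec50=2.0, seed=5)
    k = 10.0
    b = DoseResponseDataset(
        assay_type="immobilization", organism=a.organism, duration_hours=24,
        treatments=tuple(
            Treatment(label=t.label, nominal_conc=t.nominal_conc * k,
                      detection_limit=t.detection_limit, quantal=t.quantal,
                      is_control=t.is_control, is_solvent_control=t.is_solvent_control)
            for t in a.treatments
        ),
    )
    fa = fit_quantal_ll2(a, basis="nominal")
    fb = fit_quantal_ll2(b, basis="nominal")
    assert fb.ec50 == pytest.approx(k * fa.ec50, rel=1e-6)


def test_quantal_mle_beats_grid(tigriopus):
    """Oracle: the likelihood at the reported MLE dominates a parameter
    grid around it."""
    fit = fit_quantal_ll2(tigriopus)
    b_hat, loge_hat, bg = fit.params
    conc = np.array([t.geomean_measured() for t in tigriopus.exposed_treatments()])
    n = np.array([t.quantal.n_exposed for t in tigriopus.exposed_treatments()])
    k = np.array([t.quantal.n_immobile for t in tigriopus.exposed_treatments()])

    def ll(b, loge):
        p = 1 / (1 + np.exp(-b * (np.log(conc) - loge)))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))

    best_grid = max(
        ll(b, le)
        for b in np.linspace(0.5 * b_hat, 2 * b_hat, 40)
        for le in np.linspace(loge_hat - 1, loge_hat + 1, 40)
    )
    assert ll(b_hat, loge_hat) >= best_grid - 1e-9


def test_published_quantal_ec50s_inside_printed_cis(tigriopus):
    fit = fit_quantal_ll2(tigriopus)
    assert 1.4 < fit.ec50 < 2.6
    crab = fit_quantal_ll2(load_packaged_fixture("table2_bluecrab"))
    assert 6.2 < crab.ec50 < 25


def test_quantal_abbott_correction_shifts_ec50(tigriopus):
    plain = fit_quantal_ll2(tigriopus, abbott=False)
    corrected = fit_quantal_ll2(tigriopus, abbott=True)
    # backgrounds of 1/40 barely move the estimate, but not identically
    assert corrected.ec50 == pytest.approx(plain.ec50, rel=0.1)
    assert corrected.ec50 != plain.ec50


def test_quantal_degenerate_response_not_identifiable():
    ts = [Treatment(label=str(c), nominal_conc=c, detection_limit=0.2,
                    quantal=QuantalCount(20, 0)) for c in (1, 2, 4, 8)]
    ds = DoseResponseDataset("immobilization", "x", 24, tuple(ts))
    fit = fit_quantal_ll2(ds, basis="nominal")
    assert not fit.converged
    assert math.isnan(fit.ec50)


# --- Dunnett ----------------------------------------------------------------


def test_critical_value_reduces_to_student_t():
    for n, n0 in ((3, 3), (5, 4)):
        df = n + n0 - 2
        assert dunnett_critical_value([n], n0, 0.05) == pytest.approx(
            stats.t.ppf(0.975, df), abs=2e-3
        )


def test_critical_value_matches_multivariate_t_reference():
    # frozen oracle: equicoordinate two-sided 95% quantile, k=5, df=12,
    # equal correlation 1/2 (computed with mvtnorm::qmvt)
    assert dunnett_critical_value([3] * 5, 3, 0.05) == pytest.approx(2.9010, abs=2e-3)


def test_decision_rule_consistent_with_scipy_pvalues(skeletonema):
    """Dual route: scipy's Dunnett p-values and the quadrature critical
    value give the same significance calls."""
    res = dunnett_noec_loec(skeletonema, rng=np.random.default_rng(0))
    exposed = skeletonema.exposed_treatments()
    crit = dunnett_critical_value([3] * len(exposed), 3, 0.05)
    for row in res.per_treatment:
        assert row["significant"] == (abs(row["statistic"]) > crit)


def test_reconstructed_diatom_assay_noec_loec(skeletonema):
    """Replicates reconstructed from the printed mean ± SE summaries give
    the published LOEC (0.65 µg/L) and NOEC (0.45 µg/L)."""
    res = dunnett_noec_loec(skeletonema)
    assert res.loec == pytest.approx(0.65)
    assert res.noec == pytest.approx(0.45)
    assert not res.noec_is_bound


def test_overwhelming_effect_detected_alone():
    # all groups share the same within-group spread (sd 0.05) and mean,
    # except one shifted by 100 pooled-sd units
    def triple(mean):
        return (mean - 0.05, mean, mean + 0.05)

    base = [Treatment(label="SC", nominal_conc=0, is_solvent_control=True,
                      rates=triple(1.0))]
    for c in (1.0, 2.0, 4.0, 8.0):
        shift = 100 * 0.05 if c == 4.0 else 0.0
        base.append(Treatment(label=str(c), nominal_conc=c, rates=triple(1.0 + shift)))
    ds = DoseResponseDataset("algal_growth", "x", 72, tuple(base))
    res = dunnett_noec_loec(ds, basis="nominal")
    sig = {r["label"]: r["significant"] for r in res.per_treatment}
    assert sig == {"1.0": False, "2.0": False, "4.0": True, "8.0": False}


def test_dunnett_degenerate_variance_rejected():
    ts = [Treatment(label="SC", nominal_conc=0, is_solvent_control=True,
                    rates=(1.0, 1.0, 1.0))]
    ts += [Treatment(label=str(c), nominal_conc=c, rates=(1.0, 1.0, 1.0))
           for c in (1, 2, 4, 8)]
    ds = DoseResponseDataset("algal_growth", "x", 72, tuple(ts))
    with pytest.raises(ValidationError, match="pooled variance"):
        dunnett_noec_loec(ds, basis="nominal")


def test_no_effect_anywhere_reports_noec_bound():
    rng = np.random.default_rng(3)
    ts = [Treatment(label="SC", nominal_conc=0, is_solvent_control=True,
                    rates=tuple(rng.normal(1.0, 0.05, 3)))]
    ts += [Treatment(label=str(c), nominal_conc=c,
                     rates=tuple(rng.normal(1.0, 0.05, 3)))
           for c in (1, 2, 4, 8)]
    ds = DoseResponseDataset("algal_growth", "x", 72, tuple(ts))
    res = dunnett_noec_loec(ds, basis="nominal")
    assert res.noec_is_bound
    assert res.noec == 8.0
    assert res.loec is None
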