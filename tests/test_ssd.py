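"""SSD engine: MLE fits, information criteria, model averaging, hazard
concentrations, bootstrap, log-normality check."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from ecorisk import (
    DISTRIBUTIONS,
    bootstrap_hc_ci,
    fit_all,
    fit_distribution,
    hc_quantile,
    load_packaged_fixture,
    model_average,
    shapiro_wilk_log,
    simulate_ssd_values,
    ssd_plot_data,
)
from ecorisk.ssd import DistFit, gof_statistics


# --- single-family MLEs -----------------------------------------------------


def test_lnorm_mle_matches_grid_search():
    """Brute-force oracle: the closed-form log-normal MLE coincides with a
    dense grid search over (meanlog, sdlog)."""
    x = simulate_ssd_values("lnorm", (1.0, 0.8), 10, seed=3)
    fit = fit_distribution(x, "lnorm")
    grid_m = np.linspace(0.0, 2.0, 201)
    grid_s = np.linspace(0.3, 1.5, 121)
    best = max(
        ((m, s) for m in grid_m for s in grid_s),
        key=lambda p: stats.lognorm.logpdf(x, s=p[1], scale=np.exp(p[0])).sum(),
    )
    assert fit.params[0] == pytest.approx(best[0], abs=0.01)
    assert fit.params[1] == pytest.approx(best[1], abs=0.01)


@pytest.mark.parametrize("name", list(DISTRIBUTIONS))
def test_mle_beats_parameter_perturbations(name, acute_values):
    """The reported optimum is a local maximum of the likelihood."""
    d = DISTRIBUTIONS[name]
    params, ll, ok = d.fit(np.asarray(acute_values, dtype=float), seed=0)
    assert ok
    x = np.asarray(acute_values, dtype=float)
    for j in range(len(params)):
        for eps in (-0.05, 0.05):
            p = list(params)
            p[j] = p[j] * (1 + eps) + (0.001 * eps if p[j] == 0 else 0.0)
            if name in ("lnorm_lnorm", "llogis_llogis") and j == 0:
                p[0] = min(max(p[0], 1e-3), 1 - 1e-3)
            try:
                ll_pert = d.loglik(x, tuple(p))
            except (ValueError, FloatingPointError):
                continue
            assert ll_pert <= ll + 1e-6


def test_aicc_identity_and_mixture_penalty(acute_ssd):
    """AICc − AIC = 2k(k+1)/(n−k−1): exactly 2 for 2-parameter families
    and 20 for 5-parameter mixtures at n = 9."""
    for f in acute_ssd.fits:
        gap = 2 * f.k * (f.k + 1) / (f.n - f.k - 1)
        assert f.aicc - f.aic == pytest.approx(gap, abs=1e-9)
        assert gap == pytest.approx(2.0 if f.k == 2 else 20.0)


def test_fit_table_matches_published_reference(acute_ssd):
    """Every fit statistic agrees with the packaged reference table at
    its printed precision."""
    ref = load_packaged_fixture("table5_reference").set_index("distribution")
    for f in acute_ssd.fits:
        row = ref.loc[f.distribution]
        assert f.gof["anderson_darling"] == pytest.approx(row["anderson_darling"], abs=2e-3)
        assert f.gof["kolmogorov_smirnov"] == pytest.approx(row["kolmogorov_smirnov"], abs=1e-3)
        assert f.gof["cramer_von_mises"] == pytest.approx(row["cramer_von_mises"], abs=5e-4)
        assert f.aic == pytest.approx(row["aic"], abs=0.1)
        assert f.aicc == pytest.approx(row["aicc"], abs=0.5)
        assert f.bic == pytest.approx(row["bic"], abs=0.1)
        assert f.aicc_weight == pytest.approx(row["aicc_weight"], abs=2e-3)


def test_mixture_matches_or_beats_single_counterpart(acute_values):
    """A 2-component mixture nests its single-family counterpart, so its
    likelihood can only be equal or better."""
    for mix, single in (("lnorm_lnorm", "lnorm"), ("llogis_llogis", "llogis")):
        fm = fit_distribution(acute_values, mix)
        fs = fit_distribution(acute_values, single)
        assert fm.loglik >= fs.loglik - 1e-6


def test_fit_rejects_insufficient_or_invalid_data():
    with pytest.raises(ValueError):
        fit_distribution([1.0, 2.0, 3.0], "lnorm")  # n < k + 2
    with pytest.raises(ValueError):
        fit_distribution([1.0, -2.0, 3.0, 4.0], "lnorm")
    with pytest.raises(ValueError):
        fit_all([1, 2, 3, 4, 5], "singles")  # below the averaging floor
    # mixtures are silently excluded below n = 7
    fits = fit_all([1, 2, 3, 4, 5, 6.0], "all")
    assert {f.distribution for f in fits} == set(
        ("weibull", "llogis", "lnorm", "gamma", "lgumbel")
    )


# --- model averaging --------------------------------------------------------


def _dummy_fit(name, aicc, data=(1.0, 2.0)):
    return DistFit(distribution=name, params=(0.0, 1.0), loglik=0.0, n=9, k=2,
                   aic=aicc - 2, aicc=aicc, bic=aicc, gof={}, converged=True,
                   data=data)


def test_weight_normalization_and_symmetry():
    single = model_average([_dummy_fit("lnorm", 100.0)])
    assert single.fits[0].aicc_weight == pytest.approx(1.0)
    pair = model_average([_dummy_fit("lnorm", 100.0), _dummy_fit("llogis", 100.0)])
    assert [f.aicc_weight for f in pair.fits] == pytest.approx([0.5, 0.5])
    with pytest.raises(ValueError, match="mismatched"):
        model_average([_dummy_fit("lnorm", 100.0),
                       _dummy_fit("llogis", 100.0, data=(3.0, 4.0))])


def test_weights_sum_to_one(acute_ssd):
    assert sum(f.aicc_weight for f in acute_ssd.fits) == pytest.approx(1.0, abs=1e-12)


def test_single_lnorm_hc_is_closed_form(acute_values):
    ssd = model_average([fit_distribution(acute_values, "lnorm")])
    m, s = ssd.fits[0].params
    for p in (0.05, 0.5):
        expected = math.exp(m + s * stats.norm.ppf(p))
        for rule in ("weighted_quantile_mean", "weighted_cdf_inversion"):
            assert hc_quantile(ssd, p, rule) == pytest.approx(expected, rel=1e-8)
    assert hc_quantile(ssd, 0.5) == pytest.approx(math.exp(m), rel=1e-8)


def test_hc5_scale_equivariance(acute_values):
    """All seven families are closed under scaling, so multiplying the
    data by k multiplies the averaged HC5 by k: exactly for the
    closed-form/Newton families, and to optimizer tolerance once the
    simplex-fit mixtures join the average."""
    k = 3.7
    singles = model_average(fit_all(acute_values, "singles", seed=0))
    singles_k = model_average(fit_all([v * k for v in acute_values], "singles", seed=0))
    full = model_average(fit_all(acute_values, "all", seed=0))
    full_k = model_average(fit_all([v * k for v in acute_values], "all", seed=0))
    for rule in ("weighted_quantile_mean", "weighted_cdf_inversion"):
        assert hc_quantile(singles_k, 0.05, rule) == pytest.approx(
            k * hc_quantile(singles, 0.05, rule), rel=1e-8
        )
        assert hc_quantile(full_k, 0.05, rule) == pytest.approx(
            k * hc_quantile(full, 0.05, rule), rel=1e-4
        )


def test_zero_weight_fit_removal_is_negligible(acute_values):
    """A fit carrying essentially zero weight does not move the averaged
    HC5; dropping the sub-threshold mixtures moves it by less than their
    summed weight."""
    fits = fit_all(acute_values, "singles", seed=0)
    # append a dummy family 60 AICc above the best: weight ~ e^-30
    ghost = replace(fits[0], distribution="lnorm",
                    aicc=min(f.aicc for f in fits) + 60.0)
    with_ghost = model_average(list(fits) + [ghost])
    without = model_average(fits)
    assert hc_quantile(with_ghost, 0.05) == pytest.approx(
        hc_quantile(without, 0.05), rel=1e-6
    )

    full = model_average(fit_all(acute_values, "all", seed=0))
    dropped_w = sum(f.aicc_weight for f in full.fits if f.aicc_weight <= 1e-3)
    kept = [f for f in full.fits if f.aicc_weight > 1e-3]
    renorm = sum(f.aicc_weight for f in kept)
    hc_reduced = sum(f.aicc_weight / renorm * f.dist.ppf(0.05, f.params) for f in kept)
    assert abs(hc_reduced - hc_quantile(full, 0.05)) / hc_quantile(full, 0.05) < max(
        2 * dropped_w, 1e-6
    )


def test_parameter_recovery_lognormal():
    """At n = 100, the log-normal MLE recovers the generating parameters
    within three standard errors nearly always."""
    m, s, n = 2.0, 1.5, 100
    se_m, se_s = s / math.sqrt(n), s / math.sqrt(2 * n)
    hits = 0
    for i in range(200):
        x = simulate_ssd_values("lnorm", (m, s), n, seed=500 + i)
        params, _, _ = DISTRIBUTIONS["lnorm"].fit(x)
        hits += abs(params[0] - m) <= 3 * se_m and abs(params[1] - s) <= 3 * se_s
    assert hits >= 198  # >= 99%


# --- bootstrap --------------------------------------------------------------


@pytest.mark.parametrize("method", ["weighted_bounds", "weighted_samples"])
def test_bootstrap_deterministic_and_bracketing(acute_ssd, method):
    a = bootstrap_hc_ci(acute_ssd, 0.05, n_boot=200, seed=11, method=method)
    b = bootstrap_hc_ci(acute_ssd, 0.05, n_boot=200, seed=11, method=method)
    assert a.ci == b.ci
    assert a.ci[0] <= a.value <= a.ci[1]
    c = bootstrap_hc_ci(acute_ssd, 0.05, n_boot=200, seed=12, method=method)
    assert c.ci != a.ci  # a different seed moves the empirical percentiles


def test_bootstrap_rejects_bad_nboot(acute_ssd):
    with pytest.raises(ValueError):
        bootstrap_hc_ci(acute_ssd, 0.05, n_boot=0, seed=1)


# --- normality check --------------------------------------------------------


def test_shapiro_matches_reference_and_is_scale_invariant(acute_values):
    res = shapiro_wilk_log(acute_values)
    # cross-checked against R stats::shapiro.test on log(values)
    assert res["W"] == pytest.approx(0.94885, abs=1e-4)
    assert res["p"] == pytest.approx(0.6775, abs=1e-3)
    res_k = shapiro_wilk_log([v * 37.0 for v in acute_values])
    assert res_k["p"] == pytest.approx(res["p"], abs=1e-10)


def test_shapiro_geometric_progression_near_ideal():
    """A geometric progression is equally spaced in log space — close to
    ideal normal order statistics, so W is high and p large."""
    res = shapiro_wilk_log(np.geomspace(0.5, 400, 9))
    assert res["W"] == pytest.approx(0.9723, abs=1e-3)
    assert res["p"] > 0.5


def test_shapiro_input_validation():
    with pytest.raises(ValueError):
        shapiro_wilk_log([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        shapiro_wilk_log([1.0, -1.0, 2.0])


# --- plotting series --------------------------------------------------------


def test_plot_data_hazen_positions_and_monotone_curve(acute_ssd):
    d = ssd_plot_data(acute_ssd, taxon_labels=["a"] * 9)
    assert d["points_p"] == pytest.approx((np.arange(1, 10) - 0.5) / 9)
    assert d["points_p"][0] == pytest.approx(0.0556, abs=1e-3)
    assert np.all(np.diff(d["cdf"]) >= -1e-12)
    hc5 = hc_quantile(acute_ssd, 0.05, "weighted_cdf_inversion")
    assert float(acute_ssd.cdf(hc5)) == pytest.approx(0.05, abs=1e-6)
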