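"""End-to-end orchestration: bioassay summaries → dose-response fits →
model-averaged SSD → PNECs, mixture decomposition and risk quotients.

The full analysis runs from the packaged study fixtures alone and writes
a machine-readable JSON report (full precision) plus a short
human-readable summary (2 significant figures). All randomness flows
through the single seed in :class:`PipelineConfig`; reports embed the
package version, the seed and a hash of the configuration so a result
can be traced to its exact inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .bioassay import mass_to_molar, measured_to_nominal_ratios, summarize_growth
from .datamodel import NA2_EBDC, NA_DMDC, POLYCARBAMATE
from .dose_response import dunnett_noec_loec, fit_continuous_ll3, fit_quantal_ll2
from .io import load_packaged_fixture
from .risk import (
    MixtureComponent,
    aggregate_species_geomeans,
    derive_pnec,
    mixture_toxic_units,
    risk_quotient,
)
from .ssd import (
    bootstrap_hc_ci,
    fit_all,
    hc_quantile,
    model_average,
    plot_ssd,
    shapiro_wilk_log,
)

log = logging.getLogger("ecorisk")

__all__ = ["PipelineConfig", "run_full_analysis", "round_sig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis constants of the full risk-assessment run."""

    seed: int = 0
    n_boot: int = 10_000
    hc_proportion: float = 0.05
    uf_probabilistic: float = 10.0
    uf_conventional: float = 100.0
    alpha: float = 0.05
    averaging_rule: str = "weighted_quantile_mean"
    abbott: bool = False
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.hc_proportion < 1:
            raise ValueError("hc_proportion must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.uf_probabilistic < 1 or self.uf_conventional < 1:
            raise ValueError("uncertainty factors must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report rendering)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


_ALGAL_FIXTURES = ["table1_dunaliella", "table1_skeletonema", "table1_tetraselmis",
                   "table3_dmdc", "table3_ebdc"]
_QUANTAL_FIXTURES = ["table2_bluecrab", "table2_tigriopus"]


def _finite(x):
    return x if (isinstance(x, (int, float)) and math.isfinite(x)) else None


def _fit_to_dict(fit) -> dict:
    return {
        "model": fit.model,
        "ec50_ugL": _finite(fit.ec50),
        "ec50_ci_ugL": [_finite(v) for v in fit.ec50_ci],
        "slope": _finite(fit.slope),
        "converged": fit.converged,
        "n_treatments": fit.n_treatments,
        "concentration_basis": fit.concentration_basis,
    }


def run_full_analysis(config: PipelineConfig = PipelineConfig()) -> dict:
    """Run the complete analysis on the packaged fixtures.

    Returns the report bundle as a dict; when ``config.output_dir`` is
    set, also writes ``report.json``, ``summary.txt`` and ``ssd.png``
    there. Any stage failure aborts with the stage name and cause.
    """
    report: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
    }

    stage = "bioassay endpoints"
    try:
        log.info("stage: %s", stage)
        assays = {}
        for name in _ALGAL_FIXTURES:
            ds = load_packaged_fixture(name)
            # no usable measured concentrations: fall back to nominal
            has_measured = any(
                t.geomean_measured() is not None for t in ds.exposed_treatments()
            )
            basis = "measured_geomean" if has_measured else "nominal"
            fit = fit_continuous_ll3(ds, basis=basis)
            noec = dunnett_noec_loec(
                ds, alpha=config.alpha, basis=basis,
                rng=np.random.default_rng(config.seed),
            )
            assays[name] = {
                "organism": ds.organism,
                "summaries": summarize_growth(ds),
                "measured_to_nominal_pct": measured_to_nominal_ratios(ds),
                "fit": _fit_to_dict(fit),
                "noec_ugL": noec.noec,
                "noec_is_bound": noec.noec_is_bound,
                "loec_ugL": noec.loec,
            }
        for name in _QUANTAL_FIXTURES:
            ds = load_packaged_fixture(name)
            fit = fit_quantal_ll2(ds, basis="measured_geomean", abbott=config.abbott)
            assays[name] = {
                "organism": ds.organism,
                "measured_to_nominal_pct": measured_to_nominal_ratios(ds),
                "fit": _fit_to_dict(fit),
            }
        report["assays"] = assays
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "species sensitivity distribution"
    try:
        log.info("stage: %s (n_boot=%d, seed=%d)", stage, config.n_boot, config.seed)
        acute = load_packaged_fixture("table4_acute")
        values = [r.value for r in acute]
        taxa = [r.taxon_group for r in acute]
        fits = fit_all(values, "all", seed=config.seed)
        ssd = model_average(fits, config.averaging_rule)
        hc = bootstrap_hc_ci(
            ssd, proportion=config.hc_proportion, n_boot=config.n_boot,
            seed=config.seed,
        )
        report["ssd"] = {
            "n_species": len(values),
            "values_ugL": values,
            "model_fit_table": [
                {
                    "distribution": f.distribution,
                    **{k: v for k, v in f.gof.items()},
                    "aic": f.aic,
                    "aicc": f.aicc,
                    "bic": f.bic,
                    "delta_aic": f.delta_aic,
                    "delta_aicc": f.delta_aicc,
                    "aicc_weight": f.aicc_weight,
                }
                for f in sorted(ssd.fits, key=lambda f: f.distribution)
            ],
            "averaging_rule": config.averaging_rule,
            "hc": {
                "proportion": config.hc_proportion,
                "value_ugL": hc.value,
                "value_other_rule_ugL": hc_quantile(
                    ssd, config.hc_proportion,
                    "weighted_cdf_inversion"
                    if config.averaging_rule == "weighted_quantile_mean"
                    else "weighted_quantile_mean",
                ),
                "ci_ugL": list(hc.ci),
                "n_boot": hc.n_boot,
                "seed": hc.seed,
            },
            "shapiro_wilk_log": shapiro_wilk_log(values),
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    stage = "risk characterization"
    try:
        log.info("stage: %s", stage)
        chronic = load_packaged_fixture("table4_chronic")
        noecs = [r for r in chronic if r.endpoint == "NOEC"]
        min_noec = min(noecs, key=lambda r: r.value)
        pnec_prob = derive_pnec(hc.value, config.uf_probabilistic, "hc5_probabilistic")
        pnec_conv = derive_pnec(
            min_noec.value, config.uf_conventional, "min_noec_conventional"
        )
        # degradation-product reference PNEC: its algal chronic NOEC on the
        # measured basis, same conventional factor
        dmdc_noec = assays["table3_dmdc"]["noec_ugL"]
        pnec_dmdc = derive_pnec(
            dmdc_noec, config.uf_conventional, "min_noec_conventional"
        )

        # concentration-addition budget on the nominal molar basis
        ec50_nominal = {
            name: fit_continuous_ll3(load_packaged_fixture(name), basis="nominal").ec50
            for name in ("table1_skeletonema", "table3_dmdc", "table3_ebdc")
        }
        pc_nM = mass_to_molar(ec50_nominal["table1_skeletonema"], POLYCARBAMATE)
        dmdc_nM = mass_to_molar(ec50_nominal["table3_dmdc"], NA_DMDC)
        ebdc_nM = mass_to_molar(ec50_nominal["table3_ebdc"], NA2_EBDC)
        mixture = mixture_toxic_units(
            pc_nM, pc_nM,
            [MixtureComponent(NA_DMDC, dmdc_nM), MixtureComponent(NA2_EBDC, ebdc_nM)],
        )

        exposures = load_packaged_fixture("exposure_hiroshima")
        rqs = []
        for ex in exposures:
            targets = (
                [("probabilistic", pnec_prob), ("conventional", pnec_conv)]
                if ex.analyte == "polycarbamate"
                # the degradation product is compared against both
                # conventional PNECs (parent and its own reference value)
                else [("conventional_parent", pnec_conv), ("conventional_own", pnec_dmdc)]
            )
            for tag, pnec in targets:
                rq = risk_quotient(ex.concentration, pnec, analyte=ex.analyte)
                rqs.append(
                    {
                        "analyte": ex.analyte,
                        "location": ex.location,
                        "mec_ugL": ex.concentration,
                        "pnec_basis": tag,
                        "pnec_ugL": pnec.pnec,
                        "risk_quotient": rq.risk_quotient,
                        "exceeds": rq.exceeds,
                    }
                )
        report["risk"] = {
            "pnec_probabilistic_ugL": pnec_prob.pnec,
            "pnec_conventional_ugL": pnec_conv.pnec,
            "pnec_dmdc_reference_ugL": pnec_dmdc.pnec,
            "min_chronic_noec_ugL": min_noec.value,
            "min_chronic_noec_species": min_noec.species,
            "species_geomeans_acute": dict(
                aggregate_species_geomeans(load_packaged_fixture("table4_acute_raw"))
            ),
            "mixture_molar_ec50_nM": {
                "parent": pc_nM, "DMDC": dmdc_nM, "EBDC": ebdc_nM,
            },
            "mixture_toxic_units": {
                "component_tus": mixture["component_tus"],
                "total": mixture["total"],
                "fractions": mixture["fractions"],
            },
            "risk_quotients": rqs,
        }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    if config.output_dir is not None:
        stage = "report output"
        try:
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n"
            )
            (out / "summary.txt").write_text(render_summary(report))
            plot_ssd(
                ssd, str(out / "ssd.png"), taxon_labels=taxa, hc=hc
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    return report


def render_summary(report: dict) -> str:
    """Human-readable one-page summary at 2 significant figures."""
    r2 = round_sig
    s = report["ssd"]
    k = report["risk"]
    lines = [
        f"ecorisk {report['package_version']}  (config {report['config_hash']}, "
        f"seed {report['config']['seed']})",
        "",
        "Acute species sensitivity distribution "
        f"(n={s['n_species']} species, AICc model averaging):",
        f"  HC{int(100 * s['hc']['proportion'])} = {r2(s['hc']['value_ugL'])} ug/L "
        f"(95% CI {r2(s['hc']['ci_ugL'][0])}-{r2(s['hc']['ci_ugL'][1])}, "
        f"{s['hc']['n_boot']} bootstrap iterations)",
        f"  Shapiro-Wilk on log values: p = {s['shapiro_wilk_log']['p']:.4f}",
        "",
        "Predicted no-effect concentrations:",
        f"  probabilistic (HC5/{int(report['config']['uf_probabilistic'])}): "
        f"{r2(k['pnec_probabilistic_ugL'])} ug/L",
        f"  conventional (min NOEC {k['min_chronic_noec_ugL']} ug/L / "
        f"{int(report['config']['uf_conventional'])}): "
        f"{r2(k['pnec_conventional_ugL'])} ug/L",
        "",
        "Concentration-addition budget at the parent EC50:",
    ]
    for name, tu in k["mixture_toxic_units"]["component_tus"].items():
        lines.append(f"  {name}: {r2(tu)} toxic units")
    lines.append(f"  total: {r2(k['mixture_toxic_units']['total'])}")
    lines.append("")
    lines.append("Risk quotients (MEC/PNEC):")
    for rq in k["risk_quotients"]:
        flag = "EXCEEDS" if rq["exceeds"] else "ok"
        lines.append(
            f"  {rq['analyte']} at {rq['mec_ugL']} ug/L vs "
            f"{rq['pnec_basis']} PNEC {r2(rq['pnec_ugL'])} ug/L: "
            f"RQ = {r2(rq['risk_quotient'], 3)} [{flag}]"
        )
    lines.append("")
    return "\n".join(lines)
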