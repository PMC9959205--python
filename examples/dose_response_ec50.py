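"""Fit a log-logistic curve to an algal growth-inhibition assay.

Loads the packaged diatom assay (triplicate specific growth rates at five
concentrations plus controls), fits the concentration-response on the
geometric-mean measured concentrations, and prints the EC50 — the
concentration halving the growth rate relative to the solvent control —
with its delta-method 95% CI.
"""

from ecorisk import fit_continuous_ll3, load_packaged_fixture, summarize_growth

ds = load_packaged_fixture("table1_skeletonema")
print(f"{ds.organism}: {len(ds.exposed_treatments())} treatments + controls")
for row in summarize_growth(ds):
    print(f"  {row['label']:>8}: rate {row['rate_mean']:.2f} ± {row['rate_se']:.2f} /d")

fit = fit_continuous_ll3(ds, basis="measured_geomean")
lo, hi = fit.ec50_ci
print(f"\n72 h EC50 = {fit.ec50:.2f} µg/L (95% CI {lo:.2f}–{hi:.2f}), "
      f"slope b = {fit.slope:.1f}")
print("The EC50 is the concentration predicted to halve the diatom's "
      "specific growth rate relative to the solvent control.")
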