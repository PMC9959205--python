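"""PNECs, mixture decomposition and risk quotients.

Derives the predicted no-effect concentration two ways — probabilistic
(HC5 / 10) and conventional (minimum chronic NOEC / 100) — decomposes
the parent antifoulant's toxicity into its two degradation products by
concentration addition, and compares measured bay concentrations against
the PNECs.
"""

from ecorisk import PipelineConfig, run_full_analysis
from ecorisk.pipeline import round_sig

report = run_full_analysis(PipelineConfig(seed=0, n_boot=1000))
risk = report["risk"]

print(f"probabilistic PNEC = {round_sig(risk['pnec_probabilistic_ugL'])} µg/L "
      f"(HC5 / 10)")
print(f"conventional PNEC  = {round_sig(risk['pnec_conventional_ugL'])} µg/L "
      f"(min chronic NOEC {risk['min_chronic_noec_ugL']} µg/L "
      f"of {risk['min_chronic_noec_species']} / 100)")

tus = risk["mixture_toxic_units"]
print("\nConcentration-addition budget at the parent algal EC50:")
for name, tu in tus["component_tus"].items():
    print(f"  {name}: {tu:.2f} toxic units")
print(f"  total: {tus['total']:.2f} "
      "(≈1 means the products alone explain the parent's toxicity)")

print("\nRisk quotients (MEC / PNEC; > 1 flags ecological risk):")
for rq in risk["risk_quotients"]:
    print(f"  {rq['analyte']:>13} {rq['mec_ugL']} µg/L vs {rq['pnec_basis']:>19}: "
          f"RQ = {rq['risk_quotient']:.1f}"
          + ("  ** exceeds **" if rq["exceeds"] else ""))
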