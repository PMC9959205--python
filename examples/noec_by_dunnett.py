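"""NOEC/LOEC determination by Dunnett's many-to-one comparisons.

Each treatment's triplicate growth rates are compared against the solvent
control with the family-wise-adjusted two-sided procedure; the LOEC is
the lowest significant concentration and the NOEC the highest tested
concentration below it.
"""

from ecorisk import dunnett_noec_loec, load_packaged_fixture

ds = load_packaged_fixture("table1_skeletonema")
res = dunnett_noec_loec(ds, alpha=0.05, basis="measured_geomean")

print(f"{ds.organism}:")
for row in res.per_treatment:
    star = " *" if row["significant"] else ""
    print(f"  {row['concentration']:>5.2f} µg/L: t = {row['statistic']:6.2f}, "
          f"adjusted p = {row['p_adjusted']:.4f}{star}")
print(f"\n{res}")
print("Starred treatments differ significantly from the solvent control "
      "at the 5% family-wise level.")
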