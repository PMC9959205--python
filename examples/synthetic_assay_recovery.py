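"""Generate a synthetic algal assay and recover its EC50.

The generator draws triplicate growth curves from a known log-logistic
concentration-response with multiplicative noise; the fitted EC50 should
recover the generating value within sampling error — and exactly when
the noise is switched off.
"""

from ecorisk import fit_continuous_ll3, simulate_algal_assay

TRUE_EC50 = 0.72  # µg/L

for cv in (0.0, 0.05):
    ds = simulate_algal_assay(
        ec50=TRUE_EC50, slope=4.0, mu_control=1.53, cv=cv,
        concentrations=(0.29, 0.45, 0.65, 2.34, 4.66), seed=7,
    )
    # the generator's curve has a free (negative) lower asymptote
    fit = fit_continuous_ll3(ds, basis="nominal", lower_free=True)
    err = abs(fit.ec50 - TRUE_EC50) / TRUE_EC50 * 100
    print(f"cv = {cv:4.2f}: fitted EC50 = {fit.ec50:.4f} µg/L "
          f"(true {TRUE_EC50}; error {err:.2f}%)")
print("With cv = 0 the recovery is exact; with 5% replicate noise the "
      "error reflects triplicate sampling variation.")
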