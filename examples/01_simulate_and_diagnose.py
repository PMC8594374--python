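"""Simulate a lineage and read off the model-discriminating correlations.

Simulates the Independent Double Adder (IDA) model for 20,000 generations
and prints the diagnostic correlation suite.  Under IDA, rho(S_b, Delta_d)
and rho(s_i, S_d) vanish (two independent adders), while rho(s_i, tau_cyc)
and rho(s_i, delta_id) are negative because the initiation-to-division
interval is emergent rather than controlled.
"""
import cellcycle as cc

params = cc.default_params("ida")
lineage = cc.simulate_ida(params, n_gen=20_000, seed=1)
table = cc.extract_observables(lineage)
report = cc.correlation_suite(table)

print(f"IDA lineage: {len(table)} generations past burn-in")
for name, entry in report.coefficients.items():
    print(f"  {name:15s} = {entry.value:+.4f}  (n={entry.n}, z-SE={entry.se:.4f})")
print("\nrho_i ~ 1/2 and rho_d ~ 1/2 are the two adders; rho_id ~ 0 and")
print("rho(S_b, Delta_d) ~ 0 show initiation and division are independent.")
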