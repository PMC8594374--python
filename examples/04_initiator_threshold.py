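"""The adder phenotype emerges from balanced biosynthesis plus a threshold.

Integrates the mechanistic initiator-threshold model: an initiator protein
is produced in proportion to volume growth (dN = c* dV) and division fires
when the pool reaches N0 copies.  Because each daughter inherits N0/2
copies, every cell must synthesize N0/2 copies - hence add the fixed
volume Delta_d = N0/(2 c*) - between birth and division, independent of
its birth size: the adder.
"""
import numpy as np

import cellcycle as cc

params = cc.default_params("threshold")  # includes Poisson-like noise
lineage = cc.simulate_threshold_ida(params, n_gen=2000, seed=3)
df = lineage.steady_state()

expected = params.N0 / (2.0 * params.c_star)
rho = float(np.corrcoef(df["birth_size"], df["delta_d"])[0, 1])
print(f"threshold N0 = {params.N0:.0f} copies, concentration c* = "
      f"{params.c_star:.0f} copies/volume")
print(f"mean added size  = {df['delta_d'].mean():.4f} "
      f"(N0/(2c*) = {expected:.4f})")
print(f"rho(S_b, Delta_d) = {rho:+.4f}  (adder: 0)")
print(f"rho_d             = {cc.mother_daughter_corr(df['division_size']):+.4f}"
      "  (adder: 0.5)")
print("\nThe added size matches the threshold prediction and decorrelates")
print("from birth size: the adder is a consequence of the mechanism, not")
print("an assumption.")
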