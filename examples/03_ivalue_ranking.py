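"""I-value model comparison, and why its discriminative power is limited.

Simulates lineages with the RDA and IDA models, ranks both models on each
dataset by the determinant of their variable-quadruple correlation matrix
(I = 1 means the quadruple is mutually independent, i.e. the model's
control variables look like true controls), then enumerates all
C(18,4) = 3060 quadruples of the physiological-variable panel to show that
many combinations corresponding to no meaningful model score even higher.
"""
import cellcycle as cc

for model in ("ida", "rda"):
    lineage = cc.simulate(model, cc.default_params(model), 20_000, seed=42)
    table = cc.extract_observables(lineage)
    ranked = cc.rank_models(table, ["rda", "ida"])
    print(f"data generated by {model.upper()}:")
    for name, res in ranked:
        print(f"  I({name.upper()}) = {res.i_value:.4f}  (n={res.n})")
    enum = cc.enumerate_quadruples(table)
    best = enum.results[0]
    print(f"  enumeration of {len(enum.results)} quadruples: "
          f"generating model ranks {enum.model_ranks[model.upper()]}")
    print(f"  best quadruple {best.variable_names} with I = {best.i_value:.4f}\n")
print("The generating model wins the pairwise comparison, but arbitrary")
print("variable combinations can outrank it - the I-value alone cannot")
print("separate sound from unsound models of the cell cycle.")
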