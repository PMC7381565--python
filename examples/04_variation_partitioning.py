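"""Elastic-net variation partitioning with permutation inference.

A planted pure climatic effect (independent predictor sets) should surface
as a large, significant pure-climatic fraction and negligible soil and
historical fractions.
"""

from divpart import (
    SimulationConfig,
    gen_dataset,
    permutation_test_fractions,
    shannon,
)

cfg = SimulationConfig(
    n_sites=60, effect_sizes={"climatic": 2.0}, cross_set_correlation=0.0, seed=3
)
ds = gen_dataset(cfg)
y = shannon(ds.community)

res = permutation_test_fractions(
    y, ds.env, n_perm=199, repeats=10, repeats_null=2,
    alpha_grid=[0.1, 0.55, 1.0], n_lambda=20, seed=0,
)
print(f"full-model mean R2adj = {res.full_model_r2adj:.3f}")
print(f"{'fraction':>10} {'R2adj':>8} {'p':>6}  significant")
for k, v in res.fractions.items():
    print(f"{k:>10} {v:>8.3f} {res.pvalues[k]:>6.3f}  {res.significant[k]}")
# C/S/H are pure (independent) effects; CS/CH/SH/CSH are overlaps shared
# between sets.  Negative fractions are kept: they are differences of
# adjusted R2 values and signal negligible explanatory contribution.
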