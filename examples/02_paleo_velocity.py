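"""Derive post-glacial climate-change predictors from gridded fields.

Uses analytic planar grids (temperature rising 0.003 degC/km east and
0.004 degC/km north; LGM uniformly 4.2 degC colder) so every number below
has a closed form: gradient 0.005 degC/km, velocity 4.2/0.005 = 840 km.
"""

from divpart import derive_historical, gen_paleo_grids

cur_t, lgm_t = gen_paleo_grids(20, 20, 1.0, {"a": 0.003, "b": 0.004, "lgm_offset": -4.2})
cur_p, lgm_p = gen_paleo_grids(
    20, 20, 1.0, {"a": 0.1, "b": 0.2, "c": 800.0, "lgm_offset": -50.0, "variable": "MAP"}
)

(hv,) = derive_historical(cur_t, lgm_t, cur_p, lgm_p, sites=[("site_A", 10.2, 10.7)])
print(f"temperature anomaly TA       = {hv.TA:.2f} degC (present minus LGM)")
print(f"precipitation anomaly PA     = {hv.PA:.1f} mm")
print(f"temperature change velocity  = {hv.raw_TCV:.0f} km (log10 -> TCV = {hv.TCV:.3f})")
print(f"precipitation change velocity= {hv.raw_PCV:.0f} km (log10 -> PCV = {hv.PCV:.3f})")
# The velocity is the displacement needed to keep climate constant since the
# LGM: temporal change divided by the local spatial climate gradient.
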