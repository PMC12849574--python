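"""Trend models: quadratic volume law, AIC comparison, speed-density mixed model.

The quadratic is fitted to the five published group-mean ellipsoid
volumes against the operational-sex-ratio codes 0..200; the mixed model
relates mean flight speed to swarm density with a random intercept per
replicate, here on rows simulated from a known law.
"""

import numpy as np

from swarmkin import compare_models, fit_mixed_speed_density, fit_quadratic, generate_speed_density_rows

osr = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
volumes = np.array([388.4, 305.0, 325.5, 536.3, 612.6])  # cm^3, group means

quad = fit_quadratic(osr, volumes)
print(f"V(x) = {quad.a:.4f} x^2 + {quad.b:.4f} x + {quad.c:.4f}   (R^2 = {quad.r2:.3f})")
# the minimum near x = -b/2a ~ 53 marks male-biased swarms as the most compact

comp = compare_models(osr, volumes)
print("AIC ranking:", [(e["name"], round(e["aic"], 2)) for e in comp.entries])
print("skipped:", comp.skipped)

rows = generate_speed_density_rows(seed=3, slope=-1.5, intercept=0.84, n_rows=60)
mm = fit_mixed_speed_density(rows["density"], rows["mean_speed"], rows["replicate_id"])
print(f"speed = {mm.intercept:.3f} {mm.slope:+.3f} * density  "
      f"(SE {mm.slope_se:.3f}, pseudo-R^2 {mm.pseudo_r2:.3f})")
print(f"predicted speed at density 0.10: {mm.predict(0.1):.3f} m/s")
# the negative slope says denser swarms fly slower; the generating truth
# here was slope -1.5, intercept 0.84
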