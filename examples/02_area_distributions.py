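"""Fit the four unimodal area families to a crazy quilt and rank them by AIC.

Candidates within dAIC < 2 of the best are all plausible; Akaike weights
quantify relative support. The normal family should never be competitive
for skewed, strictly positive areas.
"""

import patchstat as ps
from patchstat.distributions import fit_all_families

quilt = ps.generate_crazy_quilt((150, 125), ps.GeneratorConfig(seed=7, target_n=300))
ranking = fit_all_families(quilt.areas, scale_factor=0.01)

print(f"{quilt.name}: n = {len(quilt.patches)}, "
      f"skewness {ps.sample_skewness(quilt.areas):+.2f}")
print(f"{'family':<10} {'dAIC':>8} {'weight':>7}  candidate")
for res in ranking.results:
    fam = res.family
    print(f"{fam:<10} {ranking.delta_aic[fam]:>8.2f} "
          f"{ranking.akaike_weights[fam]:>7.3f}  {fam in ranking.candidates}")

# The winning family varies from quilt to quilt (gamma/Weibull vs lognormal),
# just as it does across real crazy quilts; what is stable is that the areas
# are unimodal and the normal ranks last by a wide margin.
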