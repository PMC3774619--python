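# patchstat

Spatial statistics for patchwork quilt layouts: are "crazy" quilts —
patchwork deliberately sewn to look haphazard — actually statistically
random, and how do they differ from conventional quilts built from repeated
motif blocks?

`patchstat` is a Python library (with a thin `patchstat` CLI) for anyone
analysing tessellated artefacts as data: it ingests patch outlines as
polygons, and quantifies a quilt's layout along the two axes on which the
two quilt classes separate:

* **Patch areas.** Crazy quilts have a single, positively skewed,
  continuous area distribution; block quilts have a *Gaussian mixture*, one
  component per motif shape.  The package fits gamma / Weibull / lognormal
  / normal families by maximum likelihood and ranks them by AIC
  (candidates at ΔAIC < 2, Akaike weights `w_i ∝ exp(-Δ_i/2)`), fits
  *seeded* Gaussian mixtures by EM, and tests fit with a sorted-area rank
  envelope from 39 simulations (pointwise two-sided α = 2/40 = 0.05).
* **Patch centroids.** Centroid locations are modelled as a Strauss
  pairwise-interaction process with density ∝ β^n γ^s(x), where s(x)
  counts point pairs closer than the interaction radius r (γ = 1 Poisson,
  γ = 0 hard core).  The fit maximises Besag's pseudolikelihood with a
  Berman–Turner quadrature, profiling r in 0.01-cm steps over the full
  interpoint-distance range; goodness of fit uses Ripley's K through
  L = √(K/π) with isotropic edge correction and 39-simulation Monte-Carlo
  envelopes.  A profile maximiser with γ̂ > 1 is reported as model
  *rejection* (`valid=False`), the typical outcome for grid-organised
  quilts.

Because the hand-traced quilts behind the published analysis were never
deposited, the package includes a synthetic generator for both classes
(translational motif grids with Gaussian "motor-error" jitter; random
minimum-area tessellations by recursive chord splitting or Strauss-seeded
Voronoi cells) plus the published 16-quilt summary table, so the whole
pipeline is testable end to end.

## Worked example

```python
import patchstat as ps

# a synthetic crazy quilt: 90 patches tessellating a 60 x 50 cm window
quilt = ps.generate_crazy_quilt((60, 50), ps.GeneratorConfig(seed=2, target_n=90))
report = ps.analyze_quilt(quilt, ps.AnalysisConfig(seed=11))

print("patches:", report.n_patches)
print("area skewness:", round(report.skewness, 2))
print("best family:", report.family_ranking.best.family,
      "candidates:", report.family_ranking.candidates)
print("KDE bandwidth:", round(report.bandwidth, 2))
print("Gaussian-envelope deviations:", report.area_envelope.n_deviations,
      f"({report.area_envelope.pct_deviations:.1f}%)")
print("Strauss fit: gamma=%.3f r=%.2f valid=%s"
      % (report.strauss.gamma, report.strauss.r, report.strauss.valid))
```

prints

```
patches: 90
area skewness: 1.99
best family: lognormal candidates: ('lognormal',)
KDE bandwidth: 8.99
Gaussian-envelope deviations: 36 (40.0%)
Strauss fit: gamma=0.404 r=3.05 valid=True
```

Read: the areas are strongly right-skewed and unimodal (a lognormal fits
best, the normal is never a candidate), a single Gaussian is a poor area
model (40% of sorted areas leave its 39-simulation envelope), and the
centroids are well described by a soft-repulsion Strauss process
(γ̂ ≈ 0.40 at r̂ ≈ 3 cm) — the signature of an intendedly random layout.
A regular quilt run through the same pipeline shows the opposite pattern:
multimodal areas that sit inside their seeded-mixture envelope (0%
deviations) and centroids that the Strauss model rejects or that leave the
L-function envelope across most radii.

The same analysis from the shell:

```bash
patchstat simulate --quilt-class crazy --target-n 90 --window 60 50 --seed 2 -o crazy.json
patchstat analyze crazy.json -o report.json
patchstat fit-areas crazy.json --scale 0.01
```

`examples/` contains one short narrative script per capability.

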