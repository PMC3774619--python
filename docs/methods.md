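# Methods

`patchstat` asks a concrete question about tessellated artefacts: is the
layout of a patchwork quilt statistically distinguishable from the output of
a random process?  It operationalises the question with two complementary
analyses — the *distribution of patch areas* and the *spatial arrangement of
patch centroids* — and ships a synthetic generator so that both analyses can
be validated end to end even though the hand-traced museum quilts that
motivated the package were never published as data.

## Geometry

A quilt is a rectangular observation window (cm, origin top-left, y
downward) containing simple polygonal patches.  Area and centroid are
computed analytically (shoelace sum and first moments, via shapely), which
is the infinite-resolution limit of averaging pixel coordinates over a
traced raster region; the test suite bounds the discrepancy against a
0.001-cm rasterisation oracle (area within 0.5%, centroid within 0.1% of
the bounding-box diagonal).  Pixel-unit input is calibrated at ingest by a
cm-per-pixel scale estimated from both the height and the width and
averaged.  Before any spatial analysis the quilt is cropped to the smallest
axis-aligned box covering its patches, so un-patched borders do not dilute
the point pattern.

The package ships a 16-quilt summary table (8 regular, 8 crazy: patch
counts, dimensions, overall and patched areas) of the museum survey this
line of work is based on; it carries no polygon geometry and is used for
the arithmetic and rank-test checks that *are* reproducible from printed
numbers.

## Patch-area distributions

Four two-parameter families are fitted by maximum likelihood to the areas
of one quilt: gamma (shape, rate), Weibull (shape, scale), lognormal
(meanlog, sdlog) and normal (mean, MLE sd).  Normal and lognormal use their
closed-form MLEs; gamma and Weibull are fitted numerically with the
location pinned at zero (scipy).  Ranking uses AIC = 2k − 2 logL with k = 2
for every family and no small-sample correction; every family within
ΔAIC < 2 of the best is reported as a plausible candidate, and Akaike
weights w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2) quantify relative support.  Areas
are pre-scaled by 0.01 by default (0.1 is appropriate for small quilts);
ΔAIC and the weights are invariant to the common factor, which the tests
verify, so the scaling is purely numerical hygiene.

Skewness is the plain moment coefficient g1 = m3/m2^1.5 with 1/n central
moments — deliberately not bias-corrected, matching the "moments"
convention of the original analysis environment.

## Mixture models and the sorted-area envelope

Regular quilts repeat a small set of motif shapes, so their areas are
modelled as a Gaussian mixture with one component per motif category.  EM
is *seeded* from the per-category means, SDs and relative frequencies
rather than initialised blindly: unseeded, information-criterion-selected
mixtures tend to merge motifs of different shape but similar area (an
unseeded BIC path is provided for comparison, off by default).  Crazy
quilts have no categories and get a single component seeded from the
overall mean and SD; the single-component "fit" is the closed-form MLE and
bypasses EM entirely.  EM stops when the relative log-likelihood change
falls below 1e-8 (cap 1000 iterations) and raises a named error if a
component collapses below 1e-12 of the data range.

Goodness of fit is a rank envelope: 39 simulated samples of the same size
as the data are drawn from the fitted mixture (component by weight, then
Gaussian — simulations may legitimately be negative, and a skewed area
distribution forcing its Gaussian model to put mass below zero is part of
the signal); every series is sorted, and data values strictly outside the
pointwise min/max band are deviations at pointwise two-sided level
α = 2/(39+1) = 0.05.  Strict inequality is used deliberately: a value equal
to an envelope bound is not outside it.  Simulations resample category
membership multinomially (fixed per-category counts are available as an
option).  The kernel-density bandwidth reported per quilt uses
0.9·min(sd, IQR/1.34)·n^(−1/5) — the classical rule-of-thumb default of the
original analysis environment — and serves as a smoothing-demand summary:
multimodal motif-peaked data need little smoothing, broad skewed
distributions need much more.

## Strauss point-process analysis

Patch centroids are modelled as a Strauss process: density proportional to
β^n γ^s(x), with s(x) the number of point pairs closer than the interaction
radius r.  γ = 1 is Poisson, γ = 0 hard core, 0 < γ < 1 soft repulsion;
γ > 1 makes the density non-integrable, so a profile maximiser with
γ̂ > 1 is reported with `valid=False` and read as *rejection* of the
Strauss model for that pattern (never clamped).  Quilt seams impose exactly
the kind of minimum-separation constraint the model captures, which is why
crazy quilts fit it well while grid-organised regular quilts do not.

Fitting maximises Besag's pseudolikelihood.  The integral term uses a
Berman–Turner quadrature: a regular dummy grid of at least 4× the point
count *plus the data points*, with grid-cell counting weights.  Including
the data points matters — with a dummy-only grid, a strongly clustered or
lattice-like pattern can achieve complete separation between data and
dummy neighbour counts and send the pseudolikelihood to +∞ as γ → 0.  The
interaction radius is profiled over every value from the minimum to the
maximum interpoint distance in 0.01-cm steps; at each radius the
pseudolikelihood is maximised analytically in β and by golden-section
search over log γ ∈ [−20, 2].  Because neighbour counts change only when r
crosses one of the finitely many interpoint (or quadrature–data) distances,
the entire profile is computed in a single sweep over the sorted distances
with incrementally maintained count histograms (numba-compiled); a
~14,000-point profile of a 200-point pattern takes seconds.

Edge effects are handled with Ripley's isotropic correction (closed form
for rectangular windows, validated against arc-length quadrature in the
tests): pair contributions are weighted by the reciprocal of the fraction
of the pair-distance circle inside the window.  The correction is on by
default for both the pseudolikelihood counts and the K/L estimates.
Without it, profile radii comparable to the window size can reward fits
that soak up boundary inhomogeneity; if profiling uncorrected, capping the
profile at about a quarter of the window side is recommended.

Goodness of fit uses Ripley's K, K̂(r) = |W|/n² Σ_{i≠j} w_ij 1[d_ij ≤ r],
through the variance-stabilising L = √(K/π) (L = r under complete spatial
randomness; the L plotted is L(r), not L(r) − r).  Thirty-nine patterns are
simulated from the fitted model — fixed-n Metropolis–Hastings, moving one
uniformly chosen point to a uniform location and accepting with
min(1, γ^Δs); default 10⁴·n proposals after 10³·n burn-in, with an s(x)
trace available as a convergence diagnostic — and the data's L̂ is compared
against the pointwise min/max band.  The envelope is refused for invalid
(γ̂ > 1) fits: those patterns have already rejected the model, mirroring
how the original analysis treated its three non-convergent regular quilts.

### Calibration caveat of the profiled fit

Profiling r in 0.01 steps across the full interpoint range examines
thousands of candidate radii.  For patterns with genuine repulsive
structure this is harmless — parameter recovery on simulated Strauss data
(γ = 0.2, r = 5, n = 200) returns the radius to within ±0.12 in every one
of 20 replicates.  For *pure noise* (binomial/Poisson patterns) it overfits:
in 20 CSR replicates only ~40% of profiled fits land in γ̂ ∈ [0.8, 1.2],
the rest finding small radii where a handful of random close pairs mimic
clustering (γ̂ up to the e² search bound).  This is a property of the
published procedure itself, not of the implementation — the sweep agrees
with a brute-force scan of the same objective — and the corresponding
calibration test is left failing as documentation rather than silently
regularised away.  Patterns with real minimum-separation structure (all
quilts, both classes) are unaffected.

## Synthetic quilts

The generator provides the study conditions for every test:

* **Regular**: a motif template (four-patch, nine-patch or pinwheel block,
  25 cm default) tiled on a grid, every vertex perturbed by centred
  Gaussian noise.  The default jitter (0.25 cm) yields per-category area
  CVs of roughly 3–4%, the magnitude of the few-percent re-measurement
  error reported for hand-traced patches; at jitter 0 the tiling is exact
  and per-category variance vanishes.
* **Crazy**: a random tessellation with a minimum patch area (default
  4 cm²) and a target patch count (default 321, the surveyed crazy-quilt
  average).  `recursive_split` picks a patch with probability proportional
  to its area and slices it along a uniform-angle chord through a uniform
  interior point, skipping slices violating the minimum area — straight
  seams and positively skewed, unimodal areas by construction.
  `voronoi_strauss` instead tessellates around seeds drawn from a repulsive
  Strauss process (γ = 0.2 default), merging undersized cells into their
  longest-boundary neighbour.  Two mechanisms are provided deliberately:
  the historical record describes the *product*, not the production
  process, so nothing should hinge on one generative story.  An optional
  block mode tessellates sub-blocks independently, emulating the
  intermediate block/strip organisation some crazy quilts show (off by
  default).

What the generator does *not* emulate: fabric, colour, embroidery,
curved or imperfectly straight seams, sewing order, and the mild
within-block motif correlations of real piecing.  Passing tests therefore
demonstrate that the statistical machinery distinguishes the two layout
classes it models, not that it would classify any historical quilt.

## Group comparisons

Two-sample comparisons (patch counts, patched areas, KDE bandwidths,
envelope-deviation percentages) use the Mann–Whitney U with the reported
statistic min(U₁, U₂), a tie-corrected normal approximation and no
continuity correction — the asymptotic convention of the era's statistics
packages — plus Cohen's d with the pooled (n₁+n₂−2) SD.  An exact
permutation p-value is available behind a flag for small samples.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; the pipeline derives all
stage seeds from one master seed via `numpy` seed sequences, so a report
reruns bit-identically.  The test-suite and acceptance-script Monte-Carlo
studies use deliberately scaled-down problem sizes — e.g. crazy quilts of
~80–150 patches on 50–100 cm windows and shortened MH chains (2·10³
proposals per point) for envelope simulation — chosen so the full suite
runs in minutes while keeping every rate and tolerance at the values
stated above.
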