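"""Generate one quilt of each class and look at its basic geometry.

Regular quilts are a jittered translational grid of a motif block; crazy
quilts are a random tessellation with a minimum patch area.
"""

import patchstat as ps

regular = ps.generate_regular_quilt(
    ps.load_template("nine_patch"), 6, 6, ps.GeneratorConfig(seed=1)
)
crazy = ps.generate_crazy_quilt((150, 125), ps.GeneratorConfig(seed=1, target_n=300))

for quilt in (regular, crazy):
    areas = quilt.areas
    print(f"{quilt.name}:")
    print(f"  {len(quilt.patches)} patches in a "
          f"{quilt.window[0]:.0f} x {quilt.window[1]:.0f} cm window")
    print(f"  area range {areas.min():.1f} - {areas.max():.1f} cm^2, "
          f"skewness {ps.sample_skewness(areas):+.2f}")
    print(f"  patched/window area ratio {quilt.patched_area / quilt.window_area:.4f}")

# The regular quilt's areas cluster tightly per motif category (a few percent
# spread from seam jitter); the crazy quilt's areas are continuous and
# right-skewed and tile the window exactly.
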