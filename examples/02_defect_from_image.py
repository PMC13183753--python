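"""Quantify surface defects of a printlet photograph by two-stage thresholding.

Renders a synthetic top-view photograph with a known 7% void fraction,
then recovers that fraction from pixels alone: Otsu segmentation of the
printlet from the background, hole filling, and a 0.45 gray-level void
threshold inside the printlet mask.
"""

from printopt import SyntheticImageSpec, measure_image, render_printlet_image

rendered = render_printlet_image(
    SyntheticImageSpec(target_void_fraction=0.07, seed=3)
)
print(f"ground-truth void fraction: {rendered.void_fraction:.4f}")

result = measure_image(rendered.image, void_threshold=0.45)
print(f"measured defect fraction:   {result.defect_fraction:.4f} "
      f"({100 * result.defect_fraction:.1f}%)")
print(f"printlet pixels: {int(result.printlet_mask.sum())}, "
      f"void pixels: {int(result.void_mask.sum())}")
# The measured fraction is void pixels divided by all printlet pixels
# (voids and non-voids); it should match the ground truth to ~0.01.
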