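"""Full-factorial design and replicate measurements on the virtual printer.

Builds the 3-level, 4-factor design (81 combinations), prints each
combination five times on the synthetic defect surface and reports the
shape and spread of the resulting measurement table.
"""

import numpy as np

from printopt import (FactorLevels, ResponseSurface, generate_full_factorial,
                      layer_count, sample_measurements)

design = generate_full_factorial(FactorLevels())
print(f"design combinations: {len(design)}")

surface = ResponseSurface()
dataset = sample_measurements(surface, design, replicates=5, seed=0)
print(f"replicate measurements: {len(dataset)}")
print(f"defect fraction range: {dataset.y.min():.4f} - {dataset.y.max():.4f}")

low_flow = dataset.y[dataset.X[:, 3] <= 80]
high_flow = dataset.y[dataset.X[:, 3] >= 110]
print(f"mean defect at flow <= 80 mm^3/s: {low_flow.mean():.3f}")
print(f"mean defect at flow >= 110 mm^3/s: {high_flow.mean():.3f}")
# Low flow under-extrudes and leaves voids; adequate flow prints clean.

print(f"layers in a 5 mm printlet at 0.2 mm layer height: {layer_count(5, 0.2)}")
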