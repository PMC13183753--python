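"""Closed-loop adaptive design: find parameters for a targeted defect level.

Starts from 20 random grid points measured on the virtual printer, then
iterates: fit a Gaussian process to the deviations |defect - target|,
score all unexplored grid candidates with Expected Improvement, print
the argmax candidate, augment the data.  Stops when a print lands within
tolerance of the target.
"""

import numpy as np

from printopt import (ResponseSurface, SearchSpace, build_search_space,
                      make_surface_evaluator, run_adaptive_loop,
                      sample_measurements)

surface = ResponseSurface()
space = SearchSpace()
grid = build_search_space(space)
print(f"candidate grid size: {len(grid)}")

rng = np.random.default_rng(0)
initial_points = [grid[i] for i in rng.choice(len(grid), 20, replace=False)]
initial = sample_measurements(surface, initial_points, replicates=1,
                              seed=int(rng.integers(2**31)))
evaluator = make_surface_evaluator(surface, seed=int(rng.integers(2**31)))

for target, tol in [(0.0, 0.01), (0.15, 0.03)]:
    trace = run_adaptive_loop(initial, evaluator, target=target,
                              tolerance=tol, budget=30, space=space)
    print(f"\ntarget {100 * target:.0f}% defect (+-{100 * tol:.0f}%): "
          f"{trace.stop_reason} after {trace.n_evaluations} experiments")
    for rec in trace.iterations[-3:]:
        p = rec.params
        print(f"  iter {rec.iteration:2d}: speed {p.print_speed:4.0f}, "
              f"infill {p.infill_density:3.0f}, temp {p.print_temperature:4.0f}, "
              f"flow {p.flow_rate:4.0f} -> measured "
              f"{100 * rec.measured_defect:.2f}% (EI {rec.ei:.4f})")
# Each suggested experiment trades off exploitation (low predicted
# deviation) and exploration (high posterior uncertainty).
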