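"""Synthetic study generator: the virtual printer and virtual camera.

Everything the physical study measures is emulated here so the whole
pipeline can be exercised and validated end to end without hardware:

* a full-factorial design over the four varied processing parameters,
* a ground-truth defect response surface acting as a virtual printer
  (defects rise sharply once the volumetric flow rate drops below a knee,
  with minor contributions from speed, infill and temperature),
* replicate measurements with additive Gaussian noise at the ~1-2 %
  absolute level typical of image-based defect readings,
* top-view printlet photographs: a bright disc on a dark background with
  dark voids packed to a controllable area fraction, with exact
  ground-truth masks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import FEATURE_NAMES, DefectDataset

__all__ = [
    "PrintParameters",
    "FactorLevels",
    "ResponseSurface",
    "SyntheticImageSpec",
    "RenderedPrintlet",
    "generate_full_factorial",
    "evaluate_surface",
    "sample_measurements",
    "render_printlet_image",
    "layer_count",
    "make_surface_evaluator",
]


@dataclass(frozen=True)
class PrintParameters:
    """One point in the 4-dimensional processing space.

    Units: print_speed mm/s, infill_density percent, print_temperature
    degrees C, flow_rate mm^3/s.
    """

    print_speed: float
    infill_density: float
    print_temperature: float
    flow_rate: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("print parameters must be finite")
        if np.any(vals < 0):
            raise ValueError("print parameters must be non-negative")
        if self.infill_density > 100:
            raise ValueError("infill_density is a percentage and must be <= 100")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.print_speed, self.infill_density,
             self.print_temperature, self.flow_rate], dtype=float
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PrintParameters":
        s, i, t, f = (float(v) for v in arr)
        return cls(s, i, t, f)


@dataclass(frozen=True)
class FactorLevels:
    """Ordered levels per factor; defaults are the 3-level study design."""

    print_speed: tuple[float, ...] = (10.0, 30.0, 50.0)
    infill_density: tuple[float, ...] = (0.0, 20.0, 40.0)
    print_temperature: tuple[float, ...] = (180.0, 200.0, 220.0)
    flow_rate: tuple[float, ...] = (80.0, 100.0, 120.0)

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            levels = getattr(self, name)
            if len(levels) == 0:
                raise ValueError(f"factor '{name}' has an empty level list")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError(f"levels of factor '{name}' must be strictly increasing")

    def as_dict(self) -> dict[str, tuple[float, ...]]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def generate_full_factorial(levels: FactorLevels | None = None) -> list[PrintParameters]:
    """Cartesian product of the factor levels, lexicographic in factor order.

    The default 3-level, 4-factor design yields the 81 combinations of the
    batch-printing study.
    """
    levels = levels or FactorLevels()
    combos = itertools.product(*(getattr(levels, name) for name in FEATURE_NAMES))
    return [PrintParameters(*combo) for combo in combos]


# ----------------------------------------------------------------------
# Virtual printer
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ResponseSurface:
    """Ground-truth defect response of the virtual printer.

    The dominant effect is under-extrusion: below a knee in volumetric
    flow rate the surface climbs a logistic ramp from a near-zero baseline
    to a high-defect plateau.  Speed and temperature contribute small
    V-shaped penalties away from their sweet spots and sparse infill adds
    a small offset.  Values are clipped to [0, 1].
    """

    baseline: float = 0.003
    flow_amplitude: float = 0.4
    flow_knee: float = 90.0
    flow_width: float = 5.0
    speed_center: float = 30.0
    speed_slope: float = 5e-4      # defect fraction per mm/s away from center
    infill_slope: float = 0.005    # scaled by (100 - infill)/100
    temp_center: float = 200.0
    temp_slope: float = 4e-4       # defect fraction per degC away from center
    noise_sd: float = 0.015        # replicate measurement noise, absolute

    def true_defect(self, params: PrintParameters) -> float:
        """Noise-free defect fraction at a parameter point."""
        flow_term = self.flow_amplitude / (
            1.0 + math.exp((params.flow_rate - self.flow_knee) / self.flow_width)
        )
        value = (
            self.baseline
            + flow_term
            + self.speed_slope * abs(params.print_speed - self.speed_center)
            + self.infill_slope * (100.0 - params.infill_density) / 100.0
            + self.temp_slope * abs(params.print_temperature - self.temp_center)
        )
        return float(np.clip(value, 0.0, 1.0))


def evaluate_surface(
    surface: ResponseSurface,
    params: PrintParameters,
    with_noise: bool = False,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Evaluate the virtual printer at one parameter point.

    With noise enabled, adds a Gaussian measurement error of standard
    deviation ``surface.noise_sd`` and clips back to [0, 1].
    """
    value = surface.true_defect(params)
    if with_noise:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        value += gen.normal(0.0, surface.noise_sd)
    return float(np.clip(value, 0.0, 1.0))


def sample_measurements(
    surface: ResponseSurface,
    design: list[PrintParameters],
    replicates: int = 5,
    seed: int | np.random.Generator | None = None,
) -> DefectDataset:
    """Print each design point ``replicates`` times on the virtual printer."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, targets, comb_idx, rep_idx = [], [], [], []
    for ci, params in enumerate(design):
        for r in range(replicates):
            rows.append(params.as_array())
            targets.append(evaluate_surface(surface, params, with_noise=True, rng=rng))
            comb_idx.append(ci)
            rep_idx.append(r)
    return DefectDataset(
        X=np.array(rows),
        y=np.array(targets),
        combination_index=np.array(comb_idx),
        replicate=np.array(rep_idx),
    )


def make_surface_evaluator(
    surface: ResponseSurface, seed: int | None = None, with_noise: bool = True
):
    """Callable ``PrintParameters -> measured defect`` wrapping the surface.

    A single seeded generator is shared across calls so that a sequence of
    measurements is reproducible.
    """
    rng = np.random.default_rng(seed)

    def evaluator(params: PrintParameters) -> float:
        return evaluate_surface(surface, params, with_noise=with_noise, rng=rng)

    return evaluator


# ----------------------------------------------------------------------
# Virtual camera
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for a synthetic top-view printlet photograph."""

    width: int = 192
    height: int = 192
    center: tuple[float, float] = (96.0, 96.0)   # (row, col)
    radius: float = 80.0
    target_void_fraction: float = 0.0
    void_radius_range: tuple[float, float] = (3.0, 7.0)
    foreground_level: float = 0.8
    void_level: float = 0.1
    background_level: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.center
        if not (self.radius <= r <= self.height - self.radius
                and self.radius <= c <= self.width - self.radius):
            raise ValueError("disc does not fit inside the image")
        if not 0.0 <= self.target_void_fraction <= 1.0:
            raise ValueError("target void fraction must lie in [0, 1]")
        if self.void_radius_range[0] > self.void_radius_range[1]:
            raise ValueError("void radius range must be (min, max)")
        if not (self.foreground_level > self.void_level
                and self.foreground_level > self.background_level):
            raise ValueError("foreground must be brighter than voids and background")


@dataclass
class RenderedPrintlet:
    """A rendered image plus its exact ground truth."""

    image: np.ndarray          # float image in [0, 1], shape (H, W)
    printlet_mask: np.ndarray  # bool, the disc
    void_mask: np.ndarray      # bool, subset of printlet_mask
    void_fraction: float       # |void_mask| / |printlet_mask|, exact


def render_printlet_image(spec: SyntheticImageSpec) -> RenderedPrintlet:
    """Render a printlet photograph with a known void area fraction.

    Voids are non-overlapping dark discs placed by rejection sampling
    strictly inside the printlet; overlap is tolerated after 1000 failed
    placements so generation always terminates.  The achieved fraction is
    guaranteed within +-0.01 of the target for targets up to 0.5.
    """
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0:spec.height, 0:spec.width]
    dist2 = (rr - spec.center[0]) ** 2 + (cc - spec.center[1]) ** 2
    disc = dist2 <= spec.radius**2
    disc_px = int(disc.sum())

    void = np.zeros_like(disc)
    rmin, rmax = spec.void_radius_range
    margin = 2.0
    if spec.radius - rmin - margin <= 0:
        raise ValueError("void radii too large for the disc: nothing can be placed")

    placed: list[tuple[float, float, float]] = []
    target = spec.target_void_fraction
    achieved = 0.0
    rejections = 0
    total_attempts = 0
    # half a small void underestimates the coarsest step we can take
    while target - achieved > 0.5 * math.pi * rmin**2 / disc_px:
        total_attempts += 1
        if total_attempts > 200_000:
            raise ValueError(
                f"cannot reach void fraction {target}: packing limit hit "
                f"at {achieved:.3f}"
            )
        deficit = (target - achieved) * disc_px
        r = rng.uniform(rmin, rmax)
        # shrink the last voids so we never overshoot the +-0.01 band
        r = min(r, math.sqrt(max(deficit, math.pi * rmin**2) / math.pi))
        max_off = spec.radius - r - margin
        if max_off <= 0:
            raise ValueError("void radius exceeds the printlet disc")
        # uniform position inside the allowed concentric disc
        ang = rng.uniform(0.0, 2.0 * math.pi)
        rad = max_off * math.sqrt(rng.uniform())
        vr = spec.center[0] + rad * math.sin(ang)
        vc = spec.center[1] + rad * math.cos(ang)
        if rejections <= 1000:
            overlaps = any(
                (vr - pr) ** 2 + (vc - pc) ** 2 < (r + pradius) ** 2
                for pr, pc, pradius in placed
            )
            if overlaps:
                rejections += 1
                continue
        new = dist2_mask(rr, cc, vr, vc, r) & disc
        if not new.any():
            continue
        void |= new
        placed.append((vr, vc, r))
        rejections = 0
        achieved = void.sum() / disc_px

    image = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    image[disc] = spec.foreground_level
    image[void] = spec.void_level
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return RenderedPrintlet(
        image=image,
        printlet_mask=disc,
        void_mask=void,
        void_fraction=float(void.sum() / disc_px),
    )


def dist2_mask(rr: np.ndarray, cc: np.ndarray, r0: float, c0: float,
               radius: float) -> np.ndarray:
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def layer_count(part_height_mm: float, layer_height_mm: float) -> int:
    """Number of deposited layers: ceil(part height / layer height).

    A 5 mm printlet at 0.2 mm layer height gives 25 layers.
    """
    if part_height_mm <= 0 or layer_height_mm <= 0:
        raise ValueError("heights must be positive")
    return math.ceil(part_height_mm / layer_height_mm - 1e-9)
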