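"""Synthetic paired test–retest en-face angiograms with known ground truth.

Emulates the data structure of a 3x3 mm macular OCTA test–retest study:

* a central foveal avascular zone (FAZ) free of vessels;
* a stochastic branching vessel network, brighter than the speckled
  background, grown radially outward from the FAZ rim;
* a deep-layer variant rendered at lower overall signal;
* pathology as dropout of terminal vessel segments;
* two acquisitions per eye and layer sharing the vessel tree but with
  independent speckle realizations;
* an emulated manual rater who delineates the FAZ with Gaussian
  vertex jitter (the repeatability bottleneck of the manual method).

Everything is a pure function of (inputs, seed); per-eye and per-acquisition
streams are derived from the master seed through ``numpy.random.SeedSequence``
spawn keys, so cohorts are reproducible element-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.morphology import dilation, disk

from .thresholds import (
    GreyImage,
    LAYERS,
    manual_threshold_protocol,
    rasterize_polygon,
    threshold_manual_faz,
)

__all__ = [
    "SimulationConfig",
    "VesselTree",
    "EyeRecord",
    "generate_vessel_tree",
    "apply_pathology",
    "render_angiogram",
    "generate_cohort",
    "simulate_manual_rater",
    "jitter_polygon",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: 26 eyes (11 healthy, 15 with
    capillary dropout), 3x3 mm scans, 1024x1024 px export so that skeleton
    densities land on the 1e-8 scale of megapixel scans.
    """

    image_size_px: int = 1024
    mm_extent: float = 3.0
    n_healthy: int = 11
    n_pathology: int = 15
    dropout_fraction: float = 0.25
    vessel_intensity: float = 110.0
    background_intensity: float = 30.0
    deep_signal_scale: float = 0.6      # deep-layer intensities = scale * superficial
    speckle_scale: float = 0.6          # 0 = noiseless, 1 = fully developed speckle
    rater_jitter_px: float = 2.0        # SD of the manual rater's FAZ vertex jitter
    age_range: tuple[float, float] = (20.0, 75.0)
    age_density_slope: float = 0.25     # fractional vessel-coverage loss over age_range
    target_vessel_fraction: float = 0.32
    faz_radius_mm: float = 0.25
    n_root_branches: int = 14
    step_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px < 8:
            raise ValueError("image_size_px too small to host a FAZ and vessels")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if not self.vessel_intensity > self.background_intensity:
            raise ValueError("vessel_intensity must exceed background_intensity")
        for name in ("vessel_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.n_root_branches < 1:
            raise ValueError("need at least one root branch")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max)")

    @property
    def mm_per_pixel(self) -> float:
        return self.mm_extent / self.image_size_px

    @property
    def faz_radius_px(self) -> float:
        return self.faz_radius_mm / self.mm_per_pixel


@dataclass
class _Branch:
    points: list[tuple[float, float]]
    width: int
    parent: int | None
    children: list[int] = field(default_factory=list)


@dataclass
class VesselTree:
    """A rendered branching vessel network with ground-truth coverage."""

    branches: list[_Branch]
    faz_polygon: np.ndarray          # (N, 2) row/col vertices
    mask: np.ndarray                 # rendered boolean vessel mask
    true_vessel_fraction: float
    image_size_px: int

    @property
    def branch_widths(self) -> list[int]:
        return [b.width for b in self.branches]

    @property
    def centreline_pixels(self) -> set[tuple[int, int]]:
        pixels: set[tuple[int, int]] = set()
        for br in self.branches:
            for rr, cc in _iter_polyline_pixels(br.points):
                pixels.update(zip(rr.tolist(), cc.tolist()))
        return pixels

    def terminal_indices(self) -> list[int]:
        return [i for i, b in enumerate(self.branches) if not b.children]


def _iter_polyline_pixels(points) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Dense integer pixels along a polyline with ~5 px vertex spacing.

    Each segment is oversampled at 8 points (< 1 px spacing for the default
    step), which keeps the rasterized centreline 8-connected.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) == 1:
        yield pts[:, 0].round().astype(int), pts[:, 1].round().astype(int)
        return
    a, b = pts[:-1], pts[1:]
    ts = np.linspace(0.0, 1.0, 8)
    interp = a[:, None, :] * (1.0 - ts)[None, :, None] + b[:, None, :] * ts[None, :, None]
    flat = interp.reshape(-1, 2).round().astype(int)
    yield flat[:, 0], flat[:, 1]


def _faz_polygon(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Roughly circular FAZ outline with 10% radial irregularity."""
    n_vert = 24
    centre = config.image_size_px / 2.0
    angles = np.linspace(0.0, 2.0 * math.pi, n_vert, endpoint=False)
    radii = config.faz_radius_px * (1.0 + 0.10 * rng.uniform(-1.0, 1.0, n_vert))
    rows = centre + radii * np.sin(angles)
    cols = centre + radii * np.cos(angles)
    return np.column_stack([rows, cols])


def _render_mask(
    branches: list[_Branch], faz_interior: np.ndarray, size: int
) -> np.ndarray:
    """Draw centrelines per width class, dilate to width, clear the FAZ."""
    by_width: dict[int, np.ndarray] = {}
    for br in branches:
        canvas = by_width.setdefault(br.width, np.zeros((size, size), dtype=bool))
        for rr, cc in _iter_polyline_pixels(br.points):
            ok = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            canvas[rr[ok], cc[ok]] = True
    mask = np.zeros((size, size), dtype=bool)
    for width, canvas in by_width.items():
        radius = max(0, (width - 1) // 2)
        mask |= dilation(canvas, disk(radius)) if radius else canvas
    mask &= ~faz_interior
    return mask


def _grow_walk(
    start: tuple[float, float],
    theta0: float,
    length_px: float,
    config: SimulationConfig,
    faz_barrier: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """A persistent random walk truncated at the image border or FAZ standoff."""
    size = config.image_size_px
    n_steps = max(1, int(length_px / config.step_px))
    thetas = theta0 + np.cumsum(rng.normal(0.0, 0.2, n_steps))
    steps = config.step_px * np.column_stack([np.sin(thetas), np.cos(thetas)])
    pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
    margin = 2.0
    ri = np.clip(pts[:, 0].round().astype(int), 0, size - 1)
    ci = np.clip(pts[:, 1].round().astype(int), 0, size - 1)
    bad = (
        (pts[:, 0] < margin)
        | (pts[:, 0] >= size - margin)
        | (pts[:, 1] < margin)
        | (pts[:, 1] >= size - margin)
        | faz_barrier[ri, ci]
    )
    bad[0] = False                            # roots start on the FAZ rim
    first_bad = int(np.argmax(bad)) if bad.any() else len(pts)
    return pts[: max(first_bad, 1)]


def _local_heading(points: np.ndarray, index: int) -> float:
    lo = max(0, index - 1)
    hi = min(len(points) - 1, index + 1)
    d = points[hi] - points[lo]
    return math.atan2(d[0], d[1])


def generate_vessel_tree(
    config: SimulationConfig,
    rng_seed: int,
    coverage_scale: float = 1.0,
) -> VesselTree:
    """Grow a stochastic branching tree from the FAZ rim outward.

    Three vessel generations at decreasing calibre (7, 5, 3 px; about 20, 15
    and 9 um at the 3 mm / 1024 px scale): radial arterioles seeded on the
    FAZ rim, secondary branches off them, and a capillary generation that
    keeps spawning from random parent vertices until the drawn length-times-
    width budget reaches the target coverage.  ``coverage_scale`` multiplies
    that target (this is how the age effect enters).  Capillaries are the
    terminal segments that pathology dropout later removes.
    """
    if coverage_scale <= 0:
        raise ValueError("coverage_scale must be positive")
    rng = np.random.default_rng(rng_seed)
    size = config.image_size_px
    faz_polygon = _faz_polygon(config, rng)
    faz_interior = rasterize_polygon(faz_polygon, (size, size))
    # capillary-ring standoff: centrelines keep ~8 px clear of the delineated
    # border, so the rendered vessel edge sits ~5 px outside it and only
    # outward rater-jitter excursions pick up vessel signal
    faz_standoff_px = 8
    faz_barrier = dilation(faz_interior, disk(faz_standoff_px))
    w_root, w_mid, w_cap = 7, 5, 3           # odd calibres render symmetrically
    target_area = coverage_scale * config.target_vessel_fraction * size * size
    centre = size / 2.0

    branches: list[_Branch] = []
    area = 0.0

    def add_branch(start, theta, length, width, parent) -> int:
        nonlocal area
        pts = _grow_walk(start, theta, length, config, faz_barrier, rng)
        branches.append(_Branch([tuple(p) for p in pts], width, parent=parent))
        idx = len(branches) - 1
        if parent is not None:
            branches[parent].children.append(idx)
        area += (len(pts) - 1) * config.step_px * width
        return idx

    for _ in range(config.n_root_branches):
        # seed on the actual (irregular) FAZ rim, offset outward so that after
        # calibre dilation the vessel edge sits a few px clear of the polygon
        k = int(rng.integers(len(faz_polygon)))
        vr, vc = faz_polygon[k]
        theta = math.atan2(vr - centre, vc - centre)
        offset = faz_standoff_px + 1.5
        start = (vr + offset * math.sin(theta), vc + offset * math.cos(theta))
        root = add_branch(start, theta, rng.uniform(0.30, 0.50) * size, w_root, None)
        pts = np.asarray(branches[root].points)
        if len(pts) < 4:
            continue
        for _ in range(1 + rng.poisson(2.5)):
            j = int(rng.integers(1, len(pts)))
            theta_c = _local_heading(pts, j) + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1)
            add_branch(tuple(pts[j]), theta_c, rng.uniform(0.15, 0.30) * size, w_mid, root)

    # capillary generation: fill the remaining coverage budget
    guard = 0
    while area < target_area and guard < 50_000:
        guard += 1
        parent = int(rng.integers(len(branches)))
        pts = np.asarray(branches[parent].points)
        if len(pts) < 3:
            continue
        j = int(rng.integers(1, len(pts)))
        theta_c = _local_heading(pts, j) + rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2)
        add_branch(tuple(pts[j]), theta_c, rng.uniform(0.08, 0.20) * size, w_cap, parent)

    mask = _render_mask(branches, faz_interior, size)
    frac = float(mask.mean())
    if frac <= 0.0:
        raise ValueError("degenerate configuration produced an empty vessel tree")
    return VesselTree(branches, faz_polygon, mask, frac, size)


def apply_pathology(
    tree: VesselTree, dropout_fraction: float, rng_seed: int
) -> VesselTree:
    """Remove a fraction of terminal segments (capillary dropout).

    The number removed is the fraction of terminal segments rounded half up;
    coverage strictly decreases for any positive dropout on a non-empty tree.
    """
    if not 0.0 <= dropout_fraction < 1.0:
        raise ValueError("dropout_fraction must lie in [0, 1)")
    if dropout_fraction == 0.0:
        return tree
    rng = np.random.default_rng(rng_seed)
    terminals = tree.terminal_indices()
    n_drop = int(math.floor(dropout_fraction * len(terminals) + 0.5))
    drop = set(rng.choice(terminals, size=n_drop, replace=False).tolist()) if n_drop else set()

    keep = [i for i in range(len(tree.branches)) if i not in drop]
    remap = {old: new for new, old in enumerate(keep)}
    new_branches = []
    for old in keep:
        br = tree.branches[old]
        new_branches.append(
            _Branch(
                list(br.points),
                br.width,
                parent=remap.get(br.parent) if br.parent is not None else None,
                children=[remap[c] for c in br.children if c in remap],
            )
        )
    size = tree.image_size_px
    faz_interior = rasterize_polygon(tree.faz_polygon, (size, size))
    mask = _render_mask(new_branches, faz_interior, size)
    return VesselTree(new_branches, tree.faz_polygon, mask, float(mask.mean()), size)


def render_angiogram(
    tree: VesselTree,
    layer: str,
    config: SimulationConfig,
    rng_seed: int,
) -> GreyImage:
    """Render the tree as an 8-bit angiogram with multiplicative speckle.

    Vessels sit at ``vessel_intensity``, background at
    ``background_intensity``; the deep layer scales both by
    ``deep_signal_scale``.  The speckle factor is
    ``1 + speckle_scale * (R - 1)`` with R Rayleigh-distributed with unit
    mean, so ``speckle_scale = 0`` is the noiseless limit and distinct seeds
    give independent noise over a shared vessel mask.
    """
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}")
    scale = 1.0 if layer == "superficial" else config.deep_signal_scale
    base = np.where(
        tree.mask,
        config.vessel_intensity * scale,
        config.background_intensity * scale,
    )
    if config.speckle_scale > 0:
        rng = np.random.default_rng(rng_seed)
        rayleigh = rng.rayleigh(scale=math.sqrt(2.0 / math.pi), size=base.shape)
        base = base * (1.0 + config.speckle_scale * (rayleigh - 1.0))
    pixels = np.clip(np.rint(base), 0, 255).astype(np.uint8)
    return GreyImage(pixels, mm_per_pixel=config.mm_per_pixel, layer=layer)


def jitter_polygon(
    faz_polygon: np.ndarray,
    rater_jitter_px: float,
    rng_seed: int,
    max_retries: int = 10,
) -> np.ndarray:
    """Radially perturb polygon vertices by Gaussian jitter of the given SD.

    A perturbation that self-intersects is redrawn (bounded retries); zero
    jitter returns the polygon unchanged.
    """
    poly = np.asarray(faz_polygon, dtype=np.float64)
    if not _ShapelyPolygon(poly).is_simple:
        raise ValueError("input FAZ polygon must be simple (non-self-intersecting)")
    if rater_jitter_px == 0.0:
        return poly.copy()
    rng = np.random.default_rng(rng_seed)
    centroid = poly.mean(axis=0)
    offsets = poly - centroid
    radii = np.hypot(offsets[:, 0], offsets[:, 1])
    unit = offsets / radii[:, None]
    for _ in range(max_retries):
        jitter = rng.normal(0.0, rater_jitter_px, size=len(poly))
        perturbed = centroid + (radii + jitter)[:, None] * unit
        if _ShapelyPolygon(perturbed).is_simple:
            return perturbed
    raise RuntimeError("could not draw a simple jittered FAZ polygon")


def simulate_manual_rater(
    faz_polygon: np.ndarray,
    image_shape: tuple[int, int],
    rater_jitter_px: float,
    rng_seed: int,
    max_retries: int = 10,
) -> np.ndarray:
    """One manual FAZ delineation: radial Gaussian vertex jitter, rasterized.

    Zero jitter reproduces the exact rasterization of the input polygon.
    """
    poly = jitter_polygon(faz_polygon, rater_jitter_px, rng_seed, max_retries)
    return rasterize_polygon(poly, image_shape)


@dataclass
class EyeRecord:
    """One synthetic eye: paired acquisitions of both layers plus metadata."""

    subject_id: str
    eye: str                                  # OD | OS
    age: float
    group: str                                # healthy | pathology
    signal_strength: int
    tree: VesselTree
    images: dict[tuple[str, int], GreyImage]  # (layer, acquisition) -> image
    faz_polygon: np.ndarray
    rater_seeds: dict[int, tuple[int, int, int]]
    rater_jitter_px: float
    layers: tuple[str, ...] = LAYERS

    _mask_cache: dict = field(default_factory=dict, repr=False)

    @property
    def eye_id(self) -> str:
        return f"{self.subject_id}-{self.eye}"

    def rater_polygon(self, acquisition: int, repeat: int) -> np.ndarray:
        """The rater's ``repeat``-th delineation polygon for an acquisition."""
        return jitter_polygon(
            self.faz_polygon,
            self.rater_jitter_px,
            self.rater_seeds[acquisition][repeat],
        )

    def rater_mask(self, acquisition: int, repeat: int) -> np.ndarray:
        """The rater's ``repeat``-th delineation (0..2), rasterized."""
        key = (acquisition, repeat)
        if key not in self._mask_cache:
            shape = self.images[(self.layers[0], acquisition)].shape
            self._mask_cache[key] = rasterize_polygon(
                self.rater_polygon(acquisition, repeat), shape
            )
        return self._mask_cache[key]

    def _protocol_threshold(self, layer: str, acquisition: int) -> int:
        image = self.images[(layer, acquisition)]
        t1 = threshold_manual_faz(image, self.rater_mask(acquisition, 0)).threshold
        t2 = threshold_manual_faz(image, self.rater_mask(acquisition, 1)).threshold
        t3 = lambda: threshold_manual_faz(image, self.rater_mask(acquisition, 2)).threshold
        return manual_threshold_protocol(t1, t2, t3).threshold

    def manual_threshold(self, acquisition: int) -> int:
        """Manual FAZ threshold of the superficial image (repeat protocol)."""
        return self._protocol_threshold("superficial", acquisition)

    def deep_manual_threshold(self, acquisition: int) -> int:
        """Superficial FAZ selection transferred to the deep image."""
        return self._protocol_threshold("deep", acquisition)


def _eye_seed(master: int, eye_index: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=(eye_index, stream))


def _seed_int(seq: np.random.SeedSequence) -> int:
    return int(seq.generate_state(1)[0] % (2**31))


def generate_cohort(config: SimulationConfig) -> list[EyeRecord]:
    """Generate the full synthetic cohort, element-wise reproducible.

    Ages are uniform over ``age_range`` and scale down the target vessel
    coverage linearly (slope ``age_density_slope`` over the full range), so
    vessel density decreases with age by construction.  Pathology eyes get
    terminal-segment dropout on top.
    """
    n = config.n_healthy + config.n_pathology
    if n < 1:
        raise ValueError("cohort must contain at least one eye")
    meta_rng = np.random.default_rng(_seed_int(_eye_seed(config.seed, 0, 0)))
    records: list[EyeRecord] = []
    for i in range(n):
        group = "healthy" if i < config.n_healthy else "pathology"
        age = float(meta_rng.uniform(*config.age_range))
        signal = int(meta_rng.integers(9, 11))
        lo, hi = config.age_range
        span = (hi - lo) or 1.0
        coverage = 1.0 - config.age_density_slope * (age - lo) / span

        tree = generate_vessel_tree(
            config, _seed_int(_eye_seed(config.seed, i + 1, 1)), coverage_scale=coverage
        )
        if group == "pathology":
            tree = apply_pathology(
                tree, config.dropout_fraction, _seed_int(_eye_seed(config.seed, i + 1, 2))
            )
        images: dict[tuple[str, int], GreyImage] = {}
        for li, layer in enumerate(LAYERS):
            for acq in (1, 2):
                seed = _seed_int(_eye_seed(config.seed, i + 1, 10 + 2 * li + acq))
                images[(layer, acq)] = render_angiogram(tree, layer, config, seed)
        rater_seeds = {
            acq: tuple(
                _seed_int(_eye_seed(config.seed, i + 1, 20 + 3 * acq + rep))
                for rep in range(3)
            )
            for acq in (1, 2)
        }
        records.append(
            EyeRecord(
                subject_id=f"S{i // 2 + 1:02d}",
                eye="OD" if i % 2 == 0 else "OS",
                age=age,
                group=group,
                signal_strength=signal,
                tree=tree,
                images=images,
                faz_polygon=tree.faz_polygon,
                rater_seeds=rater_seeds,
                rater_jitter_px=config.rater_jitter_px,
            )
        )
    return records
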