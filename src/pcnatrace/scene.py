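"""Synthetic two-channel nuclear time-lapse generator with ground truth.

Each scene holds a population of non-motile cells on a regular grid, imaged
every 15 min on 3 Z-planes (0.2 um spacing, 0.23 um pixels) in two channels:

* red: PCNA.  Uniform nucleoplasm following the PCNA expression archetype;
  during S phase, replication foci are added as Gaussian spots whose number,
  size and brightness follow the early/mid/late-S phenotype (many small foci
  early, fewer larger brighter foci in mid S, few large foci fading out
  through late S).
* green: a protein of interest following a second archetype, optionally with
  a chromatin-pattern decoration (peripheral rim / perinucleolar rings).

Nuclei are ellipses whose area grows linearly over interphase.  During M the
nuclear mask is replaced by a larger rounded whole-cell mask and nuclear mean
levels drop by the archetype's mitotic-dilution factor.  The out-of-focus
Z-planes are Gaussian-blurred copies of the focal plane; constant background
and additive Gaussian read noise are applied per plane.  All randomness
derives from the scene seed, so a fixed seed gives a bit-identical scene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .archetypes import MCM6, PCNA, ExpressionArchetype, evaluate_archetype
from .cycle import S_SUBPHASES, CyclePopulationParams, PhaseTimeline, sample_timeline


class SceneError(ValueError):
    """Invalid scene specification (overlapping cells, out-of-bounds nuclei, ...)."""


@dataclass(frozen=True)
class FociSubphaseParams:
    """Replication-focus statistics for one S subphase.

    ``peak_ratio_*`` give the focus-peak to nucleoplasm intensity ratio at the
    start/end of the subphase; a ratio ramp within the subphase models the
    mid-S brightening and the late-S fading of foci.  ``radius_ramps`` grows
    focus radii across the subphase (mid S); otherwise radii are drawn once
    per focus from the range.  Placement is uniform within the nucleus or
    biased to the nuclear periphery (late S).
    """

    count_range: tuple[int, int]
    radius_px_range: tuple[float, float]
    peak_ratio_start: float
    peak_ratio_end: float
    placement: str = "uniform"
    radius_ramps: bool = False

    def __post_init__(self):
        if self.count_range[0] > self.count_range[1] or self.count_range[0] < 1:
            raise ValueError("invalid focus count range")
        if self.radius_px_range[0] > self.radius_px_range[1] or self.radius_px_range[0] <= 0:
            raise ValueError("invalid focus radius range")
        if min(self.peak_ratio_start, self.peak_ratio_end) < 1.0:
            raise ValueError("peak ratios must be >= 1 (relative to nucleoplasm)")
        if self.placement not in ("uniform", "peripheral"):
            raise ValueError(f"unknown placement {self.placement!r}")

    @property
    def mean_count(self) -> float:
        return 0.5 * (self.count_range[0] + self.count_range[1])

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.radius_px_range[0] + self.radius_px_range[1])


@dataclass(frozen=True)
class FociModel:
    """Early/mid/late-S replication-focus phenotype.

    Defaults encode "many and small" foci in early S through "fewer and
    larger" in mid/late S; the within-subphase intensity ramps are tuned so
    that the mean Sobel-gradient trace of a rendered nucleus reproduces the
    canonical shape: a steep rise at S entry, a ~2 h gently decreasing early-S
    plateau, a continuous ~3.5 h rise through mid S peaking at the mid/late
    boundary, and a ~1.5 h decline to the S end.
    """

    early: FociSubphaseParams = FociSubphaseParams(
        count_range=(120, 180), radius_px_range=(2.0, 3.0),
        peak_ratio_start=2.8, peak_ratio_end=2.0)
    mid: FociSubphaseParams = FociSubphaseParams(
        count_range=(25, 40), radius_px_range=(4.0, 6.0),
        peak_ratio_start=3.0, peak_ratio_end=4.0, radius_ramps=True)
    late: FociSubphaseParams = FociSubphaseParams(
        count_range=(8, 15), radius_px_range=(6.0, 9.0),
        peak_ratio_start=4.0, peak_ratio_end=1.0, placement="peripheral")

    def __post_init__(self):
        if not self.early.mean_count > self.mid.mean_count > self.late.mean_count:
            raise ValueError("focus counts must decrease early > mid > late")
        if not self.late.mean_radius > self.early.mean_radius:
            raise ValueError("late-S foci must be larger than early-S foci")

    def subphase(self, name: str) -> FociSubphaseParams:
        return {"early": self.early, "mid": self.mid, "late": self.late}[name]


@dataclass(frozen=True)
class SceneSpec:
    """All parameters of a synthetic time-lapse scene."""

    n_cells: int = 50
    image_shape: tuple[int, int] | None = None  # (H, W); None -> fit the cell grid
    pixel_size_um: float = 0.23
    frame_interval_min: float = 15.0
    n_z: int = 3
    z_spacing_um: float = 0.2
    n_frames: int | None = None  # None -> cover the longest cycle
    cycle_params: CyclePopulationParams = CyclePopulationParams()
    foci: FociModel | None = FociModel()
    red_archetype: ExpressionArchetype = PCNA
    green_archetype: ExpressionArchetype = MCM6
    background: float = 120.0
    noise_sd: float = 50.0
    nuclear_radius_px: float = 30.0  # mean radius at G1 start
    nuclear_growth: float = 1.6      # area factor over interphase
    intensity_scale: float = 2000.0  # counts at relative level 1.0
    mitotic_radius_factor: float = 1.25
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise SceneError("n_cells must be >= 1")
        if self.frame_interval_min <= 0:
            raise SceneError("frame interval must be > 0")
        if self.n_z < 1 or self.z_spacing_um <= 0 or self.pixel_size_um <= 0:
            raise SceneError("invalid acquisition geometry")
        if self.noise_sd < 0 or self.background < 0 or self.intensity_scale <= 0:
            raise SceneError("invalid intensity parameters")
        if self.nuclear_radius_px <= 2 or self.nuclear_growth < 1:
            raise SceneError("invalid nuclear geometry")

    # -- layout ------------------------------------------------------------
    @property
    def max_cell_radius_px(self) -> float:
        interphase = self.nuclear_radius_px * math.sqrt(self.nuclear_growth) * 1.25
        mitotic = self.nuclear_radius_px * math.sqrt(self.nuclear_growth) * self.mitotic_radius_factor
        return max(interphase, mitotic)

    @property
    def patch_half_px(self) -> int:
        """Half-size of the per-cell rendering patch (covers the largest mask)."""
        return int(math.ceil(self.max_cell_radius_px)) + 4

    @property
    def grid_pitch_px(self) -> int:
        return 2 * self.patch_half_px + 2

    def layout(self) -> tuple[tuple[int, int], np.ndarray]:
        """((H, W), cell centers) for the default grid placement."""
        cols = int(math.ceil(math.sqrt(self.n_cells)))
        rows = int(math.ceil(self.n_cells / cols))
        pitch = self.grid_pitch_px
        shape = (rows * pitch, cols * pitch)
        if self.image_shape is not None:
            if self.image_shape[0] < shape[0] or self.image_shape[1] < shape[1]:
                raise SceneError(
                    f"image shape {self.image_shape} cannot hold {self.n_cells} "
                    f"cells of radius {self.max_cell_radius_px:.0f} px "
                    f"(needs at least {shape})")
            shape = tuple(self.image_shape)
        centers = np.array([
            ((i // cols) * pitch + pitch / 2, (i % cols) * pitch + pitch / 2)
            for i in range(self.n_cells)
        ], dtype=float)
        return shape, centers


@dataclass
class Scene:
    """A rendered time-lapse: image stack, labelled masks, ground truth, spec."""

    stack: np.ndarray        # (T, Z, C, H, W) uint16
    masks: np.ndarray        # (T, H, W) uint16; 0 = background, cell ids from 1
    timelines: tuple[PhaseTimeline, ...]
    spec: SceneSpec

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.stack.shape[0]) * self.spec.frame_interval_min

    @property
    def n_cells(self) -> int:
        return len(self.timelines)


# ---------------------------------------------------------------------------
# per-cell static geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _CellGeometry:
    eccentricity: float       # a/b aspect ratio, >= 1
    theta: float              # orientation, radians
    nucleoli: np.ndarray      # (2, 2) unit-ellipse coordinates


def _cell_geometry(seed: int, cell_index: int) -> _CellGeometry:
    rng = np.random.default_rng([seed, cell_index, 11])
    ecc = float(rng.uniform(1.0, 1.2))
    theta = float(rng.uniform(0, math.pi))
    ang = rng.uniform(0, 2 * math.pi, size=2)
    rad = rng.uniform(0.25, 0.5, size=2)
    nucleoli = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    return _CellGeometry(ecc, theta, nucleoli)


@dataclass(frozen=True)
class _FociLayout:
    positions: np.ndarray     # (N, 2) unit-ellipse coordinates
    radius_jitter: np.ndarray  # (N,) in [0, 1]
    amp_jitter: np.ndarray     # (N,) multiplicative, around 1


def _foci_layout(seed: int, cell_index: int, subphase: str,
                 params: FociSubphaseParams) -> _FociLayout:
    """Focus layout, frozen within one cell's S subphase."""
    idx = S_SUBPHASES.index(subphase)
    rng = np.random.default_rng([seed, cell_index, 23 + idx])
    n = int(rng.integers(params.count_range[0], params.count_range[1] + 1))
    u = rng.random(n)
    if params.placement == "peripheral":
        rho = np.sqrt(0.55 + 0.40 * u)      # annulus, biased to the rim
    else:
        rho = 0.92 * np.sqrt(u)             # uniform over the nucleus interior
    ang = rng.uniform(0, 2 * math.pi, size=n)
    positions = np.column_stack([rho * np.cos(ang), rho * np.sin(ang)])
    return _FociLayout(
        positions=positions,
        radius_jitter=rng.random(n),
        amp_jitter=rng.uniform(0.8, 1.2, size=n),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_axes(spec: SceneSpec, timeline: PhaseTimeline, geom: _CellGeometry,
                  t: float) -> tuple[float, float]:
    """Semi-axes of the nucleus at time t (area grows linearly over interphase)."""
    tau = min(t, timeline.m_start) / timeline.m_start
    scale = math.sqrt(1.0 + (spec.nuclear_growth - 1.0) * tau)
    r = spec.nuclear_radius_px * scale
    return r * geom.eccentricity ** 0.5, r / geom.eccentricity ** 0.5


def _patch_half(spec: SceneSpec) -> int:
    return spec.patch_half_px


def _unit_coords(half: int, a: float, b: float, theta: float):
    """(u, v) unit-ellipse coordinates on a (2*half+1)^2 local pixel grid."""
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    ct, st = math.cos(theta), math.sin(theta)
    u = (x * ct + y * st) / a
    v = (-x * st + y * ct) / b
    return u, v, x, y


def _pattern_weight(spec: SceneSpec, geom: _CellGeometry, u, v, inside) -> np.ndarray:
    """Multiplicative chromatin-pattern texture with mean 1 over the nucleus."""
    pattern = spec.green_archetype.chromatin_pattern
    rho = np.hypot(u, v)
    w = np.ones_like(rho)
    amp = 0.35
    if pattern == "late-replicating":
        w += amp * ((rho > 0.78) & (rho <= 1.0))
    if pattern in ("late-replicating", "perinucleolar"):
        for cx, cy in geom.nucleoli:
            d = np.hypot(u - cx, v - cy)
            w += amp * (np.abs(d - 0.18) < 0.07)
    mean = w[inside].mean() if inside.any() else 1.0
    return w / mean


def _render_cell(spec: SceneSpec, timeline: PhaseTimeline, geom: _CellGeometry,
                 cell_index: int, t: float):
    """Noise-free local patch for one cell at time t.

    Returns ``(red, green, mask)`` on the local grid, or None if the cell is
    no longer present (past its cycle end).
    """
    if t >= timeline.cycle_end:
        return None
    half = _patch_half(spec)
    phase = timeline.phase_of(t)
    red_level = evaluate_archetype(spec.red_archetype, timeline, t)
    green_level = evaluate_archetype(spec.green_archetype, timeline, t)
    red_val = spec.intensity_scale * red_level
    green_val = spec.intensity_scale * green_level

    if phase == "M":
        # rounded whole-cell mask, uniform diluted signal
        a_m, b_m = _ellipse_axes(spec, timeline, geom, timeline.m_start)
        r = spec.mitotic_radius_factor * math.sqrt(a_m * b_m)
        u, v, x, y = _unit_coords(half, r, r, 0.0)
        inside = (u * u + v * v) <= 1.0
        red = np.where(inside, red_val, 0.0)
        green = np.where(inside, green_val, 0.0)
        return red, green, inside

    a, b = _ellipse_axes(spec, timeline, geom, t)
    u, v, x, y = _unit_coords(half, a, b, geom.theta)
    inside = (u * u + v * v) <= 1.0

    red = np.where(inside, red_val, 0.0)
    green = np.where(inside, green_val * _pattern_weight(spec, geom, u, v, inside), 0.0)
    green[~inside] = 0.0

    if spec.foci is not None and phase == "S":
        sub = timeline.subphase_of(t)
        params = spec.foci.subphase(sub)
        layout = _foci_layout(spec.seed, cell_index, sub, params)
        sub_start, sub_end = timeline.subphase_interval(sub)
        progress = (t - sub_start) / (sub_end - sub_start)
        ratio = params.peak_ratio_start + progress * (
            params.peak_ratio_end - params.peak_ratio_start)
        amp0 = max(ratio - 1.0, 0.0) * red_val
        r_lo, r_hi = params.radius_px_range
        if params.radius_ramps:
            radii = (r_lo + progress * (r_hi - r_lo)) * (
                0.9 + 0.2 * layout.radius_jitter)
        else:
            radii = r_lo + layout.radius_jitter * (r_hi - r_lo)
        # focus centres in local pixel coordinates
        ct, st = math.cos(geom.theta), math.sin(geom.theta)
        px = layout.positions[:, 0] * a * ct - layout.positions[:, 1] * b * st
        py = layout.positions[:, 0] * a * st + layout.positions[:, 1] * b * ct
        size = 2 * half + 1
        for fx, fy, rad, aj in zip(px, py, radii, layout.amp_jitter):
            amp = amp0 * aj
            if amp <= 0:
                continue
            sigma = rad / 2.0
            w = int(math.ceil(3 * sigma))
            cx, cy = int(round(fx)) + half, int(round(fy)) + half
            x0, x1 = max(cx - w, 0), min(cx + w + 1, size)
            y0, y1 = max(cy - w, 0), min(cy + w + 1, size)
            if x0 >= x1 or y0 >= y1:
                continue
            gy, gx = np.mgrid[y0:y1, x0:x1].astype(float)
            spot = amp * np.exp(-((gx - half - fx) ** 2 + (gy - half - fy) ** 2)
                                / (2 * sigma * sigma))
            red[y0:y1, x0:x1] += spot
        red[~inside] = 0.0  # foci live inside the nucleus
    return red, green, inside


def _assemble_planes(clean: np.ndarray, spec: SceneSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """(Z, C, H, W) uint16 planes from a noise-free (C, H, W) focal frame."""
    n_z, (c, h, w) = spec.n_z, clean.shape
    focal = (n_z - 1) // 2
    out = np.empty((n_z, c, h, w), dtype=np.uint16)
    for z in range(n_z):
        for ch in range(c):
            plane = clean[ch] if z == focal else ndimage.gaussian_filter(clean[ch], 1.0)
            plane = plane + spec.background
            if spec.noise_sd > 0:
                plane = plane + rng.normal(0.0, spec.noise_sd, size=plane.shape)
            out[z, ch] = np.clip(np.rint(plane), 0, 65535).astype(np.uint16)
    return out


def render_frame(spec: SceneSpec, timeline: PhaseTimeline, t: float,
                 cell_index: int = 0, center: tuple[float, float] | None = None):
    """Render one cell into a full frame at time ``t`` (on the frame grid).

    Returns ``(planes, mask)`` with ``planes`` of shape (Z, C, H, W) uint16
    and ``mask`` a boolean nuclear (or mitotic whole-cell) mask.  The image
    shape is taken from the spec (or sized to the single cell).
    """
    if t < 0 or abs(t / spec.frame_interval_min - round(t / spec.frame_interval_min)) > 1e-9:
        raise SceneError(f"t={t} is not on the {spec.frame_interval_min}-min frame grid")
    if spec.image_shape is not None:
        shape = spec.image_shape
    else:
        pitch = spec.grid_pitch_px
        shape = (pitch, pitch)
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    geom = _cell_geometry(spec.seed, cell_index)
    clean = np.zeros((2,) + tuple(shape))
    mask = np.zeros(tuple(shape), dtype=bool)
    patch = _render_cell(spec, timeline, geom, cell_index, t)
    if patch is not None:
        red, green, inside = patch
        half = _patch_half(spec)
        cy, cx = int(round(center[0])), int(round(center[1]))
        y0, x0 = cy - half, cx - half
        y1, x1 = cy + half + 1, cx + half + 1
        if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
            raise SceneError("nucleus exceeds image bounds")
        clean[0, y0:y1, x0:x1] += red
        clean[1, y0:y1, x0:x1] += green
        mask[y0:y1, x0:x1] = inside
    frame_index = int(round(t / spec.frame_interval_min))
    rng = np.random.default_rng([spec.seed, 101, frame_index])
    return _assemble_planes(clean, spec, rng), mask


def generate_scene(spec: SceneSpec) -> Scene:
    """Render a full synthetic time-lapse for ``spec.n_cells`` cells.

    All cells start G1 at t = 0 (each real cell is followed from its own
    division, so a common origin loses no generality) and disappear after
    their cycle end.  Raises :class:`SceneError` on overlapping cells or
    nuclei exceeding the image bounds.
    """
    shape, centers = spec.layout()
    timelines = tuple(
        sample_timeline(spec.cycle_params, np.random.default_rng([spec.seed, i, 7]))
        for i in range(spec.n_cells)
    )
    geoms = [_cell_geometry(spec.seed, i) for i in range(spec.n_cells)]
    if spec.n_frames is not None:
        n_frames = int(spec.n_frames)
    else:
        n_frames = int(math.ceil(max(tl.cycle_end for tl in timelines)
                                 / spec.frame_interval_min)) + 1
    half = _patch_half(spec)
    stack = np.empty((n_frames, spec.n_z, 2) + tuple(shape), dtype=np.uint16)
    masks = np.zeros((n_frames,) + tuple(shape), dtype=np.uint16)

    for f in range(n_frames):
        t = f * spec.frame_interval_min
        clean = np.zeros((2,) + tuple(shape))
        label = masks[f]
        for i, (tl, geom) in enumerate(zip(timelines, geoms)):
            patch = _render_cell(spec, tl, geom, i, t)
            if patch is None:
                continue
            red, green, inside = patch
            cy, cx = int(round(centers[i][0])), int(round(centers[i][1]))
            y0, x0 = cy - half, cx - half
            y1, x1 = cy + half + 1, cx + half + 1
            if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
                raise SceneError(f"cell {i + 1}: nucleus exceeds image bounds")
            region = label[y0:y1, x0:x1]
            if np.any(region[inside] != 0):
                raise SceneError(f"cell {i + 1} overlaps another cell")
            region[inside] = i + 1
            clean[0, y0:y1, x0:x1] += red
            clean[1, y0:y1, x0:x1] += green
        rng = np.random.default_rng([spec.seed, 101, f])
        stack[f] = _assemble_planes(clean, spec, rng)
    return Scene(stack=stack, masks=masks, timelines=timelines, spec=spec)
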