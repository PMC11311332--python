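"""Cell-cycle temporal alignment and population averaging.

Cells have variable cycle and phase lengths, so intensities cannot be
compared at raw times.  The alignment chain is:

1. unit-time normalization: divide each cell's frame times by its cycle
   length, so every cycle spans [0, 1];
2. per-phase alignment: map each phase affinely onto the population-average
   phase interval, so phase boundaries coincide across cells;
3. linear interpolation of every aligned trace onto a common grid
   (two-nearest-point linear interpolation, i.e. the two-point FORECAST
   line; values are clamped at the grid edges);
4. rescaling of the common axis by the mean cycle duration (hours) and
   population averaging (mean, sample SD, n), optionally min-max scaled
   to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycle import PHASES, PhaseTimeline

DEFAULT_GRID_SIZE = 64  # ~ mean cycle length / frame interval


def normalize_cycle(times_min, cycle_length_min: float | None = None) -> np.ndarray:
    """Divide frame times by the cell's cycle length -> unit time in [0, 1].

    ``cycle_length_min`` defaults to the last frame time (the movie-based
    mitosis-to-mitosis measurement), making the final normalized time
    exactly 1.  Intensities are untouched by this transform.
    """
    times = np.asarray(times_min, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if cycle_length_min is None:
        cycle_length_min = float(times[-1])
    if not cycle_length_min > 0:
        raise ValueError("cycle length must be > 0")
    return times / cycle_length_min


def phase_proportions(timeline: PhaseTimeline,
                      cycle_length_min: float | None = None) -> np.ndarray:
    """(G1, S, G2, M) proportions of one cell's cycle (sum to 1)."""
    L = float(cycle_length_min) if cycle_length_min is not None else timeline.cycle_end
    if not 0 < timeline.m_start < L:
        raise ValueError("cycle length must exceed the M start")
    props = np.array([
        timeline.s_start,
        timeline.s_end - timeline.s_start,
        timeline.m_start - timeline.s_end,
        L - timeline.m_start,
    ]) / L
    if np.any(props <= 0):
        raise ValueError("all phases must have positive duration")
    return props


def population_proportions(proportions) -> np.ndarray:
    """Mean phase proportions over cells, renormalized to sum to 1."""
    arr = np.asarray(list(proportions), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4 or len(arr) == 0:
        raise ValueError("need an (n_cells, 4) array of phase proportions")
    mean = arr.mean(axis=0)
    return mean / mean.sum()


def _cumulative(props: np.ndarray) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(props)])


def align_phases(unit_times, cell_props, pop_props, cell_id=None) -> np.ndarray:
    """Map unit times so each phase lands on the population-average interval.

    ``cell_props`` / ``pop_props`` are (G1, S, G2, M) proportions.  The map
    is continuous, piecewise-linear on [0, 1], sends each of this cell's
    phase boundaries exactly onto the population cumulative proportions, and
    is monotone (no reordering of time points).
    """
    unit_times = np.asarray(unit_times, dtype=float)
    cell_props = np.asarray(cell_props, dtype=float)
    pop_props = np.asarray(pop_props, dtype=float)
    for name, p in zip(PHASES, cell_props):
        if p <= 0:
            who = f"cell {cell_id}: " if cell_id is not None else ""
            raise ValueError(f"{who}zero-length phase {name}")
    if np.any(pop_props <= 0) or not np.isclose(pop_props.sum(), 1.0):
        raise ValueError("population proportions must be positive and sum to 1")
    if np.any(unit_times < -1e-9) or np.any(unit_times > 1 + 1e-9):
        raise ValueError("unit times must lie in [0, 1]")
    src = _cumulative(cell_props / cell_props.sum())
    dst = _cumulative(pop_props)
    return np.interp(np.clip(unit_times, 0.0, 1.0), src, dst)


def interpolate_to_grid(aligned_times, values, grid) -> np.ndarray:
    """Piecewise-linear interpolation of an aligned trace onto a common grid.

    Exactly the two-nearest-point regression line between samples; grid
    points outside the trace's range are clamped to the nearest value.
    """
    aligned_times = np.asarray(aligned_times, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(aligned_times) < 2:
        raise ValueError("need at least two trace points to interpolate")
    if aligned_times.shape != values.shape:
        raise ValueError("times and values must match")
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("grid must lie within [0, 1]")
    return np.interp(grid, aligned_times, values)


def default_grid(n: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; attains both 0 and 1 exactly."""
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("cannot min-max scale a constant profile")
    return (values - lo) / (hi - lo)


@dataclass(frozen=True)
class NormalizedProfile:
    """Population mean +/- SD intensity on the rescaled common time axis."""

    time_h: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    pop_props: np.ndarray | None = None

    def __post_init__(self):
        for arr in (self.time_h, self.mean, self.sd, self.n):
            if np.asarray(arr).shape != np.asarray(self.time_h).shape:
                raise ValueError("profile arrays must share one grid")
        if np.any(np.asarray(self.n) < 1):
            raise ValueError("n must be >= 1 everywhere")

    @property
    def minmax_mean(self) -> np.ndarray:
        return minmax_scale(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.time_h,
            "mean": self.mean,
            "sd": self.sd,
            "n": self.n.astype(int),
            "minmax_mean": self.minmax_mean,
        })


def population_profile(resampled: np.ndarray, grid: np.ndarray,
                       mean_cycle_duration_h: float,
                       pop_props=None) -> NormalizedProfile:
    """Mean/SD profile over cells from an (n_cells, n_grid) matrix.

    The common axis is the unit grid multiplied by the mean cycle duration in
    hours, so the endpoint is the configured mean cycle length (e.g. 15.967 h
    for a 15 h 58 min cycle).
    """
    resampled = np.atleast_2d(np.asarray(resampled, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if resampled.shape[1] != len(grid):
        raise ValueError("trace matrix does not match the grid")
    if mean_cycle_duration_h <= 0:
        raise ValueError("mean cycle duration must be > 0")
    n_cells = resampled.shape[0]
    mean = resampled.mean(axis=0)
    sd = resampled.std(axis=0, ddof=1) if n_cells > 1 else np.zeros_like(mean)
    return NormalizedProfile(
        time_h=grid * mean_cycle_duration_h,
        mean=mean,
        sd=sd,
        n=np.full(len(grid), n_cells),
        pop_props=None if pop_props is None else np.asarray(pop_props, dtype=float),
    )


def build_profile(traces: pd.DataFrame, calls: dict, channel: str,
                  value: str = "mean_intensity",
                  grid_size: int = DEFAULT_GRID_SIZE,
                  mean_cycle_duration_h: float | None = None,
                  pop_props=None) -> NormalizedProfile:
    """Full alignment chain for one channel/metric over a cohort.

    ``calls`` maps cell_id -> PhaseCall (or PhaseTimeline).  The population
    phase proportions default to the cohort's own called timelines; the
    rescale duration defaults to the cohort mean cycle length.
    """
    from .traces import get_trace

    items = []
    for cell_id, call in sorted(calls.items()):
        timeline = getattr(call, "timeline", call)
        t, v = get_trace(traces, cell_id, channel, value)
        L = float(t[-1])
        items.append((cell_id, timeline, t, v, L))
    if not items:
        raise ValueError("no cells to profile")
    props = np.array([phase_proportions(tl, L) for _, tl, _, _, L in items])
    pop = population_proportions(props) if pop_props is None else np.asarray(pop_props)
    grid = default_grid(grid_size)
    matrix = np.empty((len(items), grid_size))
    for row, ((cell_id, timeline, t, v, L), cp) in enumerate(zip(items, props)):
        unit = normalize_cycle(t, L)
        aligned = align_phases(unit, cp, pop, cell_id=cell_id)
        matrix[row] = interpolate_to_grid(aligned, v, grid)
    if mean_cycle_duration_h is None:
        mean_cycle_duration_h = float(np.mean([L for *_, L in items])) / 60.0
    return population_profile(matrix, grid, mean_cycle_duration_h, pop_props=pop)
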