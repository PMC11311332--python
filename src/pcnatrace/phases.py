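"""Cell-cycle phase calling from red-channel Sobel traces.

S entry manifests as the start of a steep rise in the mean Sobel-gradient
trace (rapid formation of many small replication foci) and S exit as the end
of a steep fall (dissolution of the last large foci).  These verbal criteria
are formalized as runs of the smoothed first difference beyond a robust
threshold derived from the G1 baseline: k times the median absolute
deviation of the baseline derivative, centred on the baseline median slope
so that slow secular drift (nuclear growth, rising PCNA expression) does not
trigger calls.  The MAD is floored at a fraction of the absolute median
slope, which keeps the detector scale-free on nearly noise-free traces.

Within S, the early/mid boundary is the end of the post-rise plateau (the
first sustained positive derivative), and the mid/late boundary is the in-S
maximum of the smoothed trace (ties broken toward the earliest frame).
Mitosis boundaries are an input: mitotic rounding is obvious to a human
annotator (and known exactly for synthetic scenes), so M start and cycle end
arrive as annotations, with an advisory helper flagging candidate frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cycle import PhaseTimeline


class NoSDetected(Exception):
    """A trace with no qualifying S-phase signature (e.g. a G1-arrested cell)."""


@dataclass(frozen=True)
class CallerConfig:
    """Tunables of the changepoint caller.

    window
        Centred moving-average window (frames, odd).
    k
        Threshold in multiples of the baseline derivative MAD.
    min_run
        Minimum sustained run (frames) for a rise/fall.
    fallback_fractions
        Early/mid/late fractions of S used when subphase changepoints are
        not found (default 2/7, 3.5/7, 1.5/7).
    baseline_fraction
        Leading fraction of the pre-mitotic trace used for baseline
        derivative statistics (should lie within G1).
    drift_floor
        MAD floor, as a fraction of the absolute baseline median slope.
    min_swing_fraction
        A rise/fall run only qualifies as "steep" if its cumulative
        ascent/descent reaches this fraction of the trace's overall swing
        (in-trace maximum minus the baseline level); rejects shallow noise
        runs that merely dwell beyond the derivative threshold.
    """

    window: int = 3
    k: float = 3.0
    min_run: int = 3
    fallback_fractions: tuple[float, float, float] = (2 / 7, 3.5 / 7, 1.5 / 7)
    baseline_fraction: float = 0.25
    drift_floor: float = 0.5
    min_swing_fraction: float = 0.25

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        fr = self.fallback_fractions
        if len(fr) != 3 or min(fr) <= 0 or not math.isclose(sum(fr), 1.0, abs_tol=1e-9):
            raise ValueError("fallback fractions must be positive and sum to 1")
        if not 0 < self.baseline_fraction <= 1:
            raise ValueError("baseline_fraction must be in (0, 1]")


@dataclass(frozen=True)
class PhaseCall:
    """A called timeline plus, per boundary, how it was determined."""

    timeline: PhaseTimeline
    methods: dict[str, str] = field(default_factory=dict)


def smooth(values, window: int) -> np.ndarray:
    """Centred moving average; ends use shrinking windows; length preserved."""
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(values):
        raise ValueError(f"window {window} exceeds trace length {len(values)}")
    if window == 1:
        return values.copy()
    kernel = np.ones(window)
    sums = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values), kernel, mode="same")
    return sums / counts


def _runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as (start, stop) inclusive."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(mask) - start >= min_run:
        runs.append((start, len(mask) - 1))
    return runs


def _baseline_stats(d: np.ndarray, config: CallerConfig) -> tuple[float, float]:
    """(median slope, effective MAD) of the leading baseline of a derivative."""
    nb = max(config.min_run + 2, int(round(config.baseline_fraction * len(d))))
    base = d[:nb]
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    scale = max(mad, config.drift_floor * abs(med), 1e-12)
    return med, scale


def call_s_boundaries(times, values, m_start_min: float,
                      config: CallerConfig = CallerConfig()) -> tuple[float, float]:
    """Call (S start, S end) in minutes from one red-channel Sobel trace.

    The trace must cover one cycle from just after cytokinesis; only frames
    before ``m_start_min`` are searched.  Detection uses runs of the smoothed
    derivative beyond median +/- k*MAD of the G1 baseline; the boundary is
    localised at the first (rise) / last (fall) raw-derivative threshold
    crossing within the run, plus one frame: the first frame showing, and
    the first frame free of, foci signal.  Raises :class:`NoSDetected` when
    no qualifying rise-then-fall exists (distinct from invalid input).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("times and values must be matching 1-D arrays")
    pre = times < m_start_min
    if pre.sum() < max(4, config.window + 2):
        raise ValueError("trace too short before mitosis")
    t = times[pre]
    v = values[pre]
    sm = smooth(v, config.window)
    d = np.diff(sm)
    rd = np.diff(v)
    med, scale = _baseline_stats(d, config)
    thr_up = med + config.k * scale
    thr_dn = med - config.k * scale
    # a qualifying run must be steep overall, not merely dwell past the
    # derivative threshold: its cumulative swing must be commensurate with
    # the trace's total excursion above the baseline level
    nb = max(config.min_run + 2, int(round(config.baseline_fraction * len(sm))))
    swing = float(sm.max() - np.median(sm[:nb]))
    min_swing = config.min_swing_fraction * swing

    rises = [run for run in _runs(d > thr_up, config.min_run)
             if d[run[0]:run[1] + 1].sum() >= min_swing]
    if not rises:
        raise NoSDetected("no qualifying Sobel rise (no S phase detected)")
    r0, r1 = rises[0]
    # localise at the first substantial raw step of the run (>= a quarter of
    # its mean step); the boundary sits at that step's midpoint, which is
    # unbiased with respect to where in the frame interval S truly started
    dt = float(np.median(np.diff(t)))
    steps = rd[r0:r1 + 1]
    big = np.flatnonzero(steps >= 0.25 * steps.mean()) if steps.mean() > 0 else []
    s_start = t[r0 + (big[0] if len(big) else 0)] + dt / 2

    falls = [run for run in _runs(d < thr_dn, config.min_run)
             if run[0] > r1 and -d[run[0]:run[1] + 1].sum() >= min_swing]
    if not falls:
        raise NoSDetected("no qualifying Sobel fall (S end not detected)")
    f0, f1 = falls[-1]
    steps = rd[f0:f1 + 1]
    big = np.flatnonzero(steps <= 0.25 * steps.mean()) if steps.mean() < 0 else []
    s_end = t[f0 + (big[-1] if len(big) else len(steps) - 1)] + dt / 2

    if not s_start < s_end < m_start_min:
        raise NoSDetected("rise and fall do not bracket an S phase")
    return float(s_start), float(s_end)


def segment_s_subphases(times, values, s_bounds: tuple[float, float],
                        config: CallerConfig = CallerConfig()):
    """Call the early/mid and mid/late S boundaries within ``s_bounds``.

    After the initial steep rise, early S is the plateau/decrease; its end is
    the first sustained positive smoothed derivative.  The mid/late boundary
    is the earliest in-S maximum of the smoothed trace.  If a changepoint is
    missing or the ordering is violated, the configured fallback fractions
    are applied and the boundary is flagged ``"fallback"``.

    Returns ``(early_mid_min, mid_late_min, methods)``.
    """
    s_start, s_end = s_bounds
    if not s_start < s_end:
        raise ValueError(f"inverted S bounds ({s_start}, {s_end})")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    in_s = (times >= s_start - 1e-9) & (times <= s_end + 1e-9)
    idx = np.flatnonzero(in_s)

    def fallback():
        f_early, f_mid, _ = config.fallback_fractions
        return (s_start + f_early * (s_end - s_start),
                s_start + (f_early + f_mid) * (s_end - s_start))

    fb_em, fb_ml = fallback()
    if len(idx) < max(4, config.window + 1):
        return fb_em, fb_ml, {"early_mid": "fallback", "mid_late": "fallback"}

    i0, i1 = idx[0], idx[-1]
    sm = smooth(values, config.window)
    d = np.diff(sm)

    # skip the initial steep rise (maximal positive prefix of the derivative)
    j = i0
    while j < i1 and d[j] > 0:
        j += 1
    pos_runs = [run for run in _runs(d[j:i1] > 0, config.min_run)]
    em = times[j + pos_runs[0][0]] if pos_runs else None

    # mid/late boundary: first frame past the in-S maximum (earliest tie),
    # i.e. the first frame of the late-S decline
    ml_idx = i0 + int(np.argmax(values[i0:i1 + 1])) + 1
    ml = times[ml_idx] if i0 < ml_idx < i1 else None

    methods = {"early_mid": "changepoint", "mid_late": "changepoint"}
    if em is None or not s_start < em < s_end:
        em, methods["early_mid"] = fb_em, "fallback"
    if ml is None or not s_start < ml < s_end:
        ml, methods["mid_late"] = fb_ml, "fallback"
    if not em < ml:
        em, ml = fb_em, fb_ml
        methods = {"early_mid": "fallback", "mid_late": "fallback"}
    return float(em), float(ml), methods


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def call_phases(traces: pd.DataFrame, mitosis: pd.DataFrame,
                config: CallerConfig = CallerConfig(),
                channel: str = "red") -> tuple[dict[int, PhaseCall], list[int]]:
    """Call a full timeline per cell from red Sobel traces + mitosis annotations.

    ``mitosis`` must provide ``cell_id, m_start_min, cycle_end_min`` (manual
    annotations for real data; ground truth for synthetic scenes).  G1 is
    cytokinesis to S start and G2 is S end to M start by construction.
    Returns ``(calls, undetected_cell_ids)``; cells whose traces show no S
    signature are reported, not silently dropped.
    """
    from .traces import get_trace  # local import to avoid a cycle

    channels = set(traces["channel"].unique())
    if channel not in channels:
        raise KeyError(f"required channel {channel!r} missing (have {sorted(channels)})")
    ann = mitosis.set_index("cell_id")
    calls: dict[int, PhaseCall] = {}
    undetected: list[int] = []
    for cell_id in sorted(traces["cell_id"].unique()):
        cell_id = int(cell_id)
        if cell_id not in ann.index:
            raise ValueError(f"cell {cell_id}: no mitosis annotation")
        m_start = float(ann.loc[cell_id, "m_start_min"])
        cycle_end = float(ann.loc[cell_id, "cycle_end_min"])
        t, v = get_trace(traces, cell_id, channel, "sobel_mean")
        dt = float(np.median(np.diff(t)))
        last = float(t[-1])
        if not 0 < m_start < cycle_end:
            raise ValueError(f"cell {cell_id}: inconsistent mitosis annotation")
        if m_start > last + dt or cycle_end < last - dt:
            raise ValueError(f"cell {cell_id}: annotation outside trace extent")
        try:
            s_start, s_end = call_s_boundaries(t, v, m_start, config)
            em, ml, methods = segment_s_subphases(t, v, (s_start, s_end), config)
        except NoSDetected:
            undetected.append(cell_id)
            continue
        # the called cycle lives on the frame grid; M must keep >= 1 frame
        cycle_end_c = last
        m_start_c = min(max(_snap(m_start, dt), s_end + dt), cycle_end_c - dt)
        timeline = PhaseTimeline(
            s_start=s_start, early_mid=em, mid_late=ml, s_end=s_end,
            m_start=m_start_c, cycle_end=cycle_end_c, provenance="called")
        methods.update({"s_start": "changepoint", "s_end": "changepoint",
                        "m_start": "annotation", "cycle_end": "annotation"})
        calls[cell_id] = PhaseCall(timeline=timeline, methods=methods)
    return calls, undetected


def flag_mitosis_candidates(times, green_mean, drop_fraction: float = 0.30) -> np.ndarray:
    """Advisory: frame times after a > ``drop_fraction`` single-frame drop in
    green mean intensity (the mitotic-dilution signature)."""
    times = np.asarray(times, dtype=float)
    v = np.asarray(green_mean, dtype=float)
    prev = v[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_drop = np.where(prev > 0, (prev - v[1:]) / prev, 0.0)
    return times[1:][rel_drop > drop_fraction]
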