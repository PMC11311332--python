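"""Cell-cycle timing: population phase-duration statistics and per-cell timelines.

Phase durations of cultured HeLa cells are modelled as independent normal
distributions truncated from below, with defaults taken from live-imaging
measurements (G1 325 +/- 73 min, S 420 +/- 49 min, G2 158 +/- 45 min,
M 55 +/- 34 min; mean cycle 958 min = 15 h 58 min).  S phase is split into
early/middle/late subphases at fixed fractions (default 2 h / 3.5 h / 1.5 h
of a 7 h S phase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

PHASES = ("G1", "S", "G2", "M")
S_SUBPHASES = ("early", "mid", "late")

#: Phase durations below this multiple of their mean are rejected when
#: sampling (prevents non-positive or non-physiological durations).
TRUNCATION_FLOOR = 0.25


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CyclePopulationParams:
    """Population-level means/SDs of phase durations (minutes) and the S subphase split."""

    g1_mean: float = 325.0
    g1_sd: float = 73.0
    s_mean: float = 420.0
    s_sd: float = 49.0
    g2_mean: float = 158.0
    g2_sd: float = 45.0
    m_mean: float = 55.0
    m_sd: float = 34.0
    early_s_fraction: float = 2.0 / 7.0
    mid_s_fraction: float = 3.5 / 7.0
    late_s_fraction: float = 1.5 / 7.0

    def __post_init__(self):
        vals = (
            self.g1_mean, self.g1_sd, self.s_mean, self.s_sd,
            self.g2_mean, self.g2_sd, self.m_mean, self.m_sd,
            self.early_s_fraction, self.mid_s_fraction, self.late_s_fraction,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("cycle parameters must be finite")
        if min(self.g1_mean, self.s_mean, self.g2_mean, self.m_mean) <= 0:
            raise ValueError("phase duration means must be > 0")
        if min(self.g1_sd, self.s_sd, self.g2_sd, self.m_sd) < 0:
            raise ValueError("phase duration SDs must be >= 0")
        fr = (self.early_s_fraction, self.mid_s_fraction, self.late_s_fraction)
        if min(fr) < 0 or not math.isclose(sum(fr), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("S subphase fractions must be non-negative and sum to 1")

    @property
    def mean_cycle_minutes(self) -> float:
        return self.g1_mean + self.s_mean + self.g2_mean + self.m_mean

    @property
    def phase_means(self) -> tuple[float, float, float, float]:
        return (self.g1_mean, self.s_mean, self.g2_mean, self.m_mean)

    @property
    def phase_sds(self) -> tuple[float, float, float, float]:
        return (self.g1_sd, self.s_sd, self.g2_sd, self.m_sd)

    @property
    def subphase_fractions(self) -> tuple[float, float, float]:
        return (self.early_s_fraction, self.mid_s_fraction, self.late_s_fraction)


@dataclass(frozen=True)
class PhaseTimeline:
    """Boundary times (minutes from G1 start) of one cell's cycle.

    G1 starts at 0 by convention; the remaining boundaries must be strictly
    increasing.  ``provenance`` distinguishes generator ground truth from
    boundaries called by the phase caller.
    """

    s_start: float
    early_mid: float
    mid_late: float
    s_end: float
    m_start: float
    cycle_end: float
    provenance: str = "ground-truth"

    g1_start: float = field(default=0.0, init=False, repr=False)

    def __post_init__(self):
        seq = (0.0, self.s_start, self.early_mid, self.mid_late,
               self.s_end, self.m_start, self.cycle_end)
        if not all(math.isfinite(v) for v in seq):
            raise ValueError("timeline boundaries must be finite")
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"timeline boundaries must be strictly increasing, got {seq}")
        if self.provenance not in ("ground-truth", "called"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    # -- durations ---------------------------------------------------------
    @property
    def g1_duration(self) -> float:
        return self.s_start

    @property
    def s_duration(self) -> float:
        return self.s_end - self.s_start

    @property
    def g2_duration(self) -> float:
        return self.m_start - self.s_end

    @property
    def m_duration(self) -> float:
        return self.cycle_end - self.m_start

    def phase_interval(self, phase: str) -> tuple[float, float]:
        starts = {"G1": 0.0, "S": self.s_start, "G2": self.s_end, "M": self.m_start}
        ends = {"G1": self.s_start, "S": self.s_end, "G2": self.m_start, "M": self.cycle_end}
        if phase not in starts:
            raise KeyError(f"unknown phase {phase!r}")
        return starts[phase], ends[phase]

    def subphase_interval(self, subphase: str) -> tuple[float, float]:
        starts = {"early": self.s_start, "mid": self.early_mid, "late": self.mid_late}
        ends = {"early": self.early_mid, "mid": self.mid_late, "late": self.s_end}
        if subphase not in starts:
            raise KeyError(f"unknown S subphase {subphase!r}")
        return starts[subphase], ends[subphase]

    def phase_of(self, t: float) -> str:
        if not 0.0 <= t <= self.cycle_end:
            raise ValueError(f"t={t} outside cycle [0, {self.cycle_end}]")
        if t < self.s_start:
            return "G1"
        if t < self.s_end:
            return "S"
        if t < self.m_start:
            return "G2"
        return "M"

    def subphase_of(self, t: float) -> str:
        if self.phase_of(t) != "S":
            raise ValueError(f"t={t} is not in S phase")
        if t < self.early_mid:
            return "early"
        if t < self.mid_late:
            return "mid"
        return "late"

    def boundaries(self) -> dict[str, float]:
        return {
            "s_start": self.s_start,
            "early_mid": self.early_mid,
            "mid_late": self.mid_late,
            "s_end": self.s_end,
            "m_start": self.m_start,
            "cycle_end": self.cycle_end,
        }


def _sample_duration(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One phase duration from a normal truncated below at TRUNCATION_FLOOR * mean."""
    if sd == 0:
        return float(mean)
    a = (TRUNCATION_FLOOR * mean - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def sample_timeline(params: CyclePopulationParams, rng) -> PhaseTimeline:
    """Sample one cell's phase timeline from the population distributions.

    ``rng`` may be an integer seed or a ``numpy.random.Generator``.  Subphase
    boundaries are placed at the configured fractions of the sampled S
    duration.
    """
    rng = _as_rng(rng)
    g1 = _sample_duration(params.g1_mean, params.g1_sd, rng)
    s = _sample_duration(params.s_mean, params.s_sd, rng)
    g2 = _sample_duration(params.g2_mean, params.g2_sd, rng)
    m = _sample_duration(params.m_mean, params.m_sd, rng)
    s_start = g1
    return PhaseTimeline(
        s_start=s_start,
        early_mid=s_start + params.early_s_fraction * s,
        mid_late=s_start + (params.early_s_fraction + params.mid_s_fraction) * s,
        s_end=s_start + s,
        m_start=s_start + s + g2,
        cycle_end=s_start + s + g2 + m,
        provenance="ground-truth",
    )
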