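"""Protein expression archetypes: piecewise-linear level curves on phase coordinates.

An archetype describes the relative level of a nuclear protein over the cell
cycle as control points ``(phase, fraction-within-phase, level)``.  Evaluated
on a concrete :class:`~pcnatrace.cycle.PhaseTimeline`, the control points are
mapped to absolute times and interpolated linearly.  During mitosis the level
is multiplied by a dilution factor modelling the drop in mean nuclear signal
when the nuclear envelope breaks down and the protein disperses into the whole
cell volume; proteins that stay bound to mitotic chromatin (ORC1) are exempt.

Five archetypes are bundled, qualitatively reproducing reported dynamics of
RIF1, MCM6, ORC1, Claspin and PCNA in HeLa cells:

* RIF1 / MCM6 peak ~30 min into G1 and decay to a plateau reached at S entry
  (MCM6 with a 2.5-fold amplitude, RIF1 with minor fluctuations only);
* ORC1 rises through G1, holds a ~2 h plateau in early S, falls to a nadir at
  the start of G2 and rises again through late G2 and M;
* Claspin is low throughout G1, rises from S onset and plateaus from mid-S
  until mitotic entry;
* PCNA rises through G1 into early S, rises more slowly to the end of S and
  plateaus in G2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cycle import PHASES, PhaseTimeline

CHROMATIN_PATTERNS = ("none", "late-replicating", "perinucleolar", "mitotic-chromatin")

#: Within-phase position of the early-G1 peak of RIF1/MCM6: 30 min into a
#: 325-min mean G1.
_G1_PEAK_FRACTION = 30.0 / 325.0

#: End of the early-S plateau as a fraction of S (2 h of 7 h).
_EARLY_S_FRACTION = 2.0 / 7.0


@dataclass(frozen=True)
class ControlPoint:
    phase: str
    fraction: float
    level: float

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.level < 0 or not np.isfinite(self.level):
            raise ValueError("level must be finite and >= 0")


@dataclass(frozen=True)
class ExpressionArchetype:
    name: str
    control_points: tuple[ControlPoint, ...]
    mitotic_dilution: float = 0.5
    chromatin_pattern: str = "none"

    def __post_init__(self):
        if len(self.control_points) < 2:
            raise ValueError("need at least two control points")
        if not 0 < self.mitotic_dilution <= 1.0:
            raise ValueError("mitotic_dilution must be in (0, 1]")
        if self.chromatin_pattern not in CHROMATIN_PATTERNS:
            raise ValueError(f"unknown chromatin pattern {self.chromatin_pattern!r}")
        order = {p: i for i, p in enumerate(PHASES)}
        keys = [(order[cp.phase], cp.fraction) for cp in self.control_points]
        if any(b < a for a, b in zip(keys, keys[1:])):
            raise ValueError("control points must be ordered along the cycle")

    def knots(self, timeline: PhaseTimeline) -> tuple[np.ndarray, np.ndarray]:
        """Absolute (time, level) knots of this archetype on a cell's timeline."""
        times, levels = [], []
        for cp in self.control_points:
            start, end = timeline.phase_interval(cp.phase)
            t = start + cp.fraction * (end - start)
            if times and t <= times[-1] + 1e-9:
                # coincident knots (e.g. (G1,1,x) followed by (S,0,x)) collapse
                if abs(levels[-1] - cp.level) > 1e-9:
                    raise ValueError(
                        f"{self.name}: conflicting levels at coincident control points"
                    )
                continue
            times.append(t)
            levels.append(cp.level)
        return np.asarray(times), np.asarray(levels)


def evaluate_archetype(archetype: ExpressionArchetype, timeline: PhaseTimeline, t):
    """Relative protein level at time(s) ``t`` (minutes) on a cell's timeline.

    Piecewise-linear in the control points mapped to this cell's phase
    boundaries; constant extrapolation of the first/last level inside the
    cycle; mitotic dilution applied during M unless the archetype is flagged
    ``mitotic-chromatin``.  Times outside ``[0, cycle_end]`` are rejected.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tv = np.atleast_1d(t)
    if np.any(tv < 0) or np.any(tv > timeline.cycle_end):
        raise ValueError(f"time outside cycle [0, {timeline.cycle_end}]")
    times, levels = archetype.knots(timeline)
    out = np.interp(tv, times, levels)
    if archetype.chromatin_pattern != "mitotic-chromatin":
        out = np.where(tv >= timeline.m_start, out * archetype.mitotic_dilution, out)
    return float(out[0]) if scalar else out


def _rif1_like(name: str, peak: float, base_start: float, plateau: float,
               pattern: str) -> ExpressionArchetype:
    return ExpressionArchetype(
        name=name,
        control_points=(
            ControlPoint("G1", 0.0, base_start),
            ControlPoint("G1", _G1_PEAK_FRACTION, peak),
            ControlPoint("G1", 1.0, plateau),
            ControlPoint("S", 1.0, plateau),
            ControlPoint("G2", 1.0, plateau),
            ControlPoint("M", 1.0, plateau),
        ),
        mitotic_dilution=0.5,
        chromatin_pattern=pattern,
    )


RIF1 = _rif1_like("RIF1", peak=1.0, base_start=0.72, plateau=0.80,
                  pattern="late-replicating")

MCM6 = _rif1_like("MCM6", peak=1.0, base_start=0.45, plateau=0.40,
                  pattern="perinucleolar")

ORC1 = ExpressionArchetype(
    name="ORC1",
    control_points=(
        ControlPoint("G1", 0.0, 0.30),
        ControlPoint("G1", 1.0, 0.80),
        ControlPoint("S", _EARLY_S_FRACTION, 0.80),
        ControlPoint("G2", 0.0, 0.20),
        ControlPoint("G2", 1.0, 0.55),
        ControlPoint("M", 1.0, 0.90),
    ),
    mitotic_dilution=1.0,
    chromatin_pattern="mitotic-chromatin",
)

CLASPIN = ExpressionArchetype(
    name="Claspin",
    control_points=(
        ControlPoint("G1", 0.0, 0.15),
        ControlPoint("S", 0.0, 0.15),
        ControlPoint("S", 0.5, 1.00),
        ControlPoint("G2", 1.0, 1.00),
    ),
    mitotic_dilution=0.5,
    chromatin_pattern="none",
)

PCNA = ExpressionArchetype(
    name="PCNA",
    control_points=(
        ControlPoint("G1", 0.0, 0.30),
        ControlPoint("S", 0.0, 0.70),
        ControlPoint("S", _EARLY_S_FRACTION, 0.80),
        ControlPoint("S", 1.0, 0.95),
        ControlPoint("G2", 1.0, 0.95),
    ),
    mitotic_dilution=0.5,
    chromatin_pattern="none",
)

BUNDLED_ARCHETYPES: dict[str, ExpressionArchetype] = {
    a.name: a for a in (RIF1, MCM6, ORC1, CLASPIN, PCNA)
}
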