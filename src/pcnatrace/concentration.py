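"""Concentration calibration of normalized intensity profiles.

A fluorescence profile is relative; a single published mass-spectrometry
concentration for the same protein (measured on an asynchronous population)
anchors it to absolute units.  An asynchronous population samples the cycle
in proportion to time spent, so the anchor is the time-weighted mean of the
profile over the full cycle (uniform-age approximation); an exponential-age
weighting, in which young cells are over-represented in a growing culture,
is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .normalize import NormalizedProfile

logger = logging.getLogger(__name__)

WEIGHTINGS = ("uniform", "exponential")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration versus cycle time, in the units of the supplied scalar."""

    time_h: np.ndarray
    concentration: np.ndarray
    units: str
    calibration_factor: float
    clipped_points: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.concentration) < 0):
            raise ValueError("concentrations must be >= 0")


def _time_weighted_mean(time_h: np.ndarray, values: np.ndarray,
                        weighting: str) -> float:
    span = time_h[-1] - time_h[0]
    if weighting == "uniform":
        return float(np.trapezoid(values, time_h) / span)
    # exponential age structure: density ~ 2^(1 - tau), tau = cycle fraction
    tau = (time_h - time_h[0]) / span
    w = np.exp2(1.0 - tau)
    return float(np.trapezoid(w * values, time_h) / np.trapezoid(w, time_h))


def calibrate(profile: NormalizedProfile, ms_concentration: float,
              units: str = "nM", weighting: str = "uniform") -> ConcentrationProfile:
    """Scale a mean-intensity profile so its cycle average equals ``ms_concentration``.

    Small negative values (background-subtraction artifacts) are clipped to
    zero and counted before calibration.  Rejects profiles that are nowhere
    positive.  The output's time-weighted cycle average equals the supplied
    scalar by construction.
    """
    if ms_concentration <= 0:
        raise ValueError("mass-spec concentration must be > 0")
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    values = np.asarray(profile.mean, dtype=float)
    time_h = np.asarray(profile.time_h, dtype=float)
    if not np.any(values > 0):
        raise ValueError("profile is nowhere positive; cannot calibrate")
    clipped = int(np.sum(values < 0))
    if clipped:
        logger.info("clipped %d negative profile points to 0 before calibration", clipped)
    values = np.clip(values, 0.0, None)
    twm = _time_weighted_mean(time_h, values, weighting)
    factor = ms_concentration / twm
    return ConcentrationProfile(
        time_h=time_h,
        concentration=factor * values,
        units=units,
        calibration_factor=factor,
        clipped_points=clipped,
    )


def fold_change(profile: ConcentrationProfile,
                interphase_end_h: float | None = None) -> float:
    """Max/min concentration ratio, optionally restricted to interphase.

    The mitotic frames reflect redistribution of nuclear protein over the
    whole cell volume rather than abundance change, so fold-change statistics
    are usually quoted over interphase (pass the M-start time in hours).
    """
    mask = np.ones(len(profile.time_h), dtype=bool)
    if interphase_end_h is not None:
        mask = profile.time_h <= interphase_end_h
    vals = profile.concentration[mask]
    lo = float(vals.min())
    if lo <= 0:
        raise ValueError("fold change undefined for a profile reaching 0")
    return float(vals.max()) / lo
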