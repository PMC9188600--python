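"""Framewise voice intensity (dB) and its stability statistics.

Intensity is the energy-averaged level of the frame:

    I = 10 log10( mean(s(t)^2) / ref^2 ),   ref = 2e-5

(the conventional reference for sound pressure expressed in normalized
amplitude units). Only the SD and range of the contour are used as
features, and both are invariant to the choice of reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .audio import AudioSegment
from .errors import InsufficientFramesError, InvalidArgumentError

__all__ = ["IntensityContour", "intensity_contour", "intensity_stats"]

log = logging.getLogger(__name__)

REF_PRESSURE = 2e-5
SILENCE_FLOOR_DB = -100.0


@dataclass(frozen=True)
class IntensityContour:
    """Framewise intensity in dB; frame_times are frame centers (s)."""

    frame_times: np.ndarray
    values: np.ndarray
    window: float
    step: float
    ref_pressure: float = REF_PRESSURE


def intensity_contour(
    seg: AudioSegment, window: float = 0.032, step: float = 0.008
) -> IntensityContour:
    """Energy-averaged intensity per half-open frame [start, start + window).

    The default 32 ms window covers at least two cycles at 75 Hz; all-zero
    frames are floored at -100 dB with a logged warning.
    """
    if step > window:
        raise InvalidArgumentError("step must not exceed window")
    fs = seg.sample_rate
    nwin = int(round(window * fs))
    nstep = max(int(round(step * fs)), 1)
    if nwin > len(seg.samples):
        raise InsufficientFramesError("segment shorter than one analysis window")
    starts = np.arange(0, len(seg.samples) - nwin + 1, nstep)
    values = np.empty(len(starts))
    for i, s in enumerate(starts):
        energy = np.mean(seg.samples[s : s + nwin] ** 2)
        if energy <= 0.0:
            log.warning("silent frame at %.3f s floored at %g dB",
                        seg.origin_time + s / fs, SILENCE_FLOOR_DB)
            values[i] = SILENCE_FLOOR_DB
        else:
            values[i] = 10.0 * np.log10(energy / REF_PRESSURE**2)
    times = seg.origin_time + (starts + nwin / 2) / fs
    return IntensityContour(times, values, window, step)


def intensity_stats(c: IntensityContour) -> tuple[float, float]:
    """(sample SD, max - min) of the contour values, both in dB."""
    if len(c.values) < 2:
        raise InsufficientFramesError("need at least 2 frames for intensity stats")
    return float(np.std(c.values, ddof=1)), float(np.ptp(c.values))
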