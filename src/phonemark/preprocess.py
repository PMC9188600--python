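"""Recording standardization: uniform trim and band-pass filtering.

Sustained vowels are assumed largely stationary, so each recording is
reduced to a fixed-duration window (default 0.5 s, taken from the temporal
center to avoid onset/offset transients) and band-pass filtered with a
4th-order Butterworth between 50 Hz and 4 kHz before feature extraction.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .audio import AudioSegment
from .errors import InvalidArgumentError, TooShortError

__all__ = ["trim_uniform", "bandpass"]


def trim_uniform(seg: AudioSegment, duration: float = 0.5) -> AudioSegment:
    """Keep exactly ``round(duration * fs)`` samples from the segment center.

    Idempotent: trimming an already duration-length segment is the identity.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    n_keep = int(round(duration * seg.sample_rate))
    n = len(seg.samples)
    if n < n_keep:
        raise TooShortError(
            f"segment of {n / seg.sample_rate:.3f} s shorter than requested {duration} s"
        )
    start = (n - n_keep) // 2
    return AudioSegment(
        seg.samples[start : start + n_keep].copy(),
        seg.sample_rate,
        origin_time=seg.origin_time + start / seg.sample_rate,
    )


def bandpass(
    seg: AudioSegment,
    lo: float = 50.0,
    hi: float = 4000.0,
    order: int = 4,
    zero_phase: bool = False,
) -> AudioSegment:
    """Butterworth band-pass of the given order, same length as the input.

    Applied causally (forward only) by default; ``zero_phase=True`` applies
    it forward-backward instead (squares the magnitude response).
    """
    nyq = seg.sample_rate / 2.0
    if not 0 < lo < hi:
        raise InvalidArgumentError("need 0 < lo < hi")
    if hi >= nyq:
        raise InvalidArgumentError(f"hi = {hi} Hz must be below Nyquist ({nyq} Hz)")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass",
                              fs=seg.sample_rate, output="sos")
    if zero_phase:
        y = scipy.signal.sosfiltfilt(sos, seg.samples)
    else:
        y = scipy.signal.sosfilt(sos, seg.samples)
    return AudioSegment(np.asarray(y), seg.sample_rate, origin_time=seg.origin_time)
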