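"""Formant tracking (Burg LPC) and apparent vocal tract length.

Formants F1-F4 are estimated framewise by autoregressive (Burg) modelling:
the signal is resampled to twice the maximum formant frequency, pre-
emphasized from 50 Hz, Gaussian-windowed in 25 ms frames every 6.25 ms, and
fit with an order-10 AR model whose complex-pole angles give candidate
resonances. The apparent vocal tract length treats the tract as a uniform
tube closed at the glottis, so each formant maps to a length via the odd
quarter-wavelength relation

    VTL(F_i) = (2i - 1) c / (4 F_i),   c = 33,500 cm/s.

VTL is computed from the per-recording mean formants, giving four length
estimates per recording (one per formant index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from statsmodels.regression.linear_model import burg as _burg

from .audio import AudioSegment
from .errors import FormantFailureError, InsufficientFramesError, InvalidArgumentError

__all__ = [
    "FormantSettings",
    "FormantTrack",
    "VtlFeatures",
    "formant_track",
    "formant_stats",
    "vtl_from_formants",
]

SPEED_OF_SOUND_CM_S = 33_500.0


@dataclass(frozen=True)
class FormantSettings:
    """Burg formant-analysis settings (defaults: 5.5 kHz ceiling, 25 ms
    window, 6.25 ms step, pre-emphasis from 50 Hz, order 12: two poles per
    expected resonance in the band plus one spare pair that absorbs the
    residual source/noise spectral shaping)."""

    max_formant: float = 5500.0
    window: float = 0.025
    step: float = 0.00625
    preemph_from: float = 50.0
    lpc_order: int = 12
    max_bandwidth: float = 400.0
    min_freq: float = 90.0
    n_formants: int = 4


@dataclass
class FormantTrack:
    """Per-frame F1..F4 (Hz); NaN where a formant could not be assigned."""

    frame_times: np.ndarray
    formants: np.ndarray  # shape (n_frames, n_formants)
    settings: FormantSettings


@dataclass(frozen=True)
class VtlFeatures:
    """Apparent vocal tract length (cm) per formant index."""

    vtl: tuple[float, ...]
    mean_formants: tuple[float, ...]
    c: float = SPEED_OF_SOUND_CM_S


def _frame_candidates(frame: np.ndarray, fs: float, s: FormantSettings) -> np.ndarray:
    """Formant candidates (Hz) of one windowed frame via Burg pole angles."""
    if np.allclose(frame, 0.0):
        return np.empty(0)
    ar, _ = _burg(frame, order=s.lpc_order, demean=True)
    roots = np.roots(np.concatenate([[1.0], -ar]))
    roots = roots[np.imag(roots) > 0]  # one per conjugate pair
    freqs = np.angle(roots) * fs / (2.0 * np.pi)
    bws = -np.log(np.abs(roots)) * fs / np.pi
    keep = (freqs >= s.min_freq) & (freqs <= s.max_formant) & (bws <= s.max_bandwidth)
    return np.sort(freqs[keep])


def formant_track(seg: AudioSegment, settings: FormantSettings | None = None) -> FormantTrack:
    """Track the lowest four formants of a voiced segment.

    Raises :class:`FormantFailureError` when more than half the frames fail
    to yield four valid candidates (e.g. on noise with no resonant
    structure).
    """
    s = settings or FormantSettings()
    if seg.sample_rate < 2 * s.max_formant:
        raise InvalidArgumentError("sample rate below twice the formant ceiling")
    fs_new = 2.0 * s.max_formant
    # rational resample to the analysis rate
    from fractions import Fraction

    frac = Fraction(int(round(fs_new)), int(round(seg.sample_rate))).limit_denominator(1000)
    x = scipy.signal.resample_poly(seg.samples, frac.numerator, frac.denominator)
    fs = seg.sample_rate * frac.numerator / frac.denominator

    a = np.exp(-2.0 * np.pi * s.preemph_from / fs)
    x = np.append(x[0], x[1:] - a * x[:-1])  # pre-emphasis 1 - a z^-1

    nwin = int(round(s.window * fs))
    nstep = max(int(round(s.step * fs)), 1)
    win = scipy.signal.windows.gaussian(nwin, std=nwin / 6.0)

    frames, times = [], []
    for start in range(0, len(x) - nwin + 1, nstep):
        times.append(seg.origin_time + (start + nwin / 2) / fs)
        frames.append(x[start : start + nwin] * win)

    track = np.full((len(frames), s.n_formants), np.nan)
    n_bad = 0
    for i, frame in enumerate(frames):
        cand = _frame_candidates(frame, fs, s)
        track[i, : min(len(cand), s.n_formants)] = cand[: s.n_formants]
        if len(cand) < s.n_formants - 1:
            n_bad += 1
    # the highest formant may legitimately drop out of individual frames
    # (bandwidth rejection); only a majority of frames missing two or more
    # formants indicates absent resonant structure
    if n_bad > 0.5 * len(frames):
        raise FormantFailureError(
            f"{n_bad}/{len(frames)} frames lack {s.n_formants - 1} valid formants"
        )
    return FormantTrack(np.array(times), track, s)


def formant_stats(tr: FormantTrack) -> tuple[np.ndarray, np.ndarray]:
    """Per-formant mean and sample SD (Hz) over frames where it is present."""
    means = np.empty(tr.formants.shape[1])
    sds = np.empty(tr.formants.shape[1])
    for j in range(tr.formants.shape[1]):
        col = tr.formants[:, j]
        col = col[~np.isnan(col)]
        if len(col) < 2:
            raise InsufficientFramesError(f"formant {j + 1} present in < 2 frames")
        means[j] = np.mean(col)
        sds[j] = np.std(col, ddof=1)
    return means, sds


def vtl_from_formants(mean_formants) -> VtlFeatures:
    """Apparent vocal tract length per formant: VTL_i = (2i-1) c / (4 F_i)."""
    f = np.asarray(mean_formants, dtype=float)
    if np.any(f <= 0):
        raise InvalidArgumentError("formants must be positive")
    i = np.arange(1, len(f) + 1)
    vtl = (2 * i - 1) * SPEED_OF_SOUND_CM_S / (4.0 * f)
    return VtlFeatures(vtl=tuple(vtl), mean_formants=tuple(f))
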