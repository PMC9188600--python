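"""Glottal-cycle detection and periodicity/stability measures.

The perturbation measures quantify cycle-to-cycle instability of vocal-fold
vibration: jitter (period perturbation, absolute in seconds and relative to
the mean period), shimmer (amplitude perturbation, in dB and relative), the
standard deviation of the instantaneous pitch f0_i = 1/T_i, and the
harmonics-to-noise ratio derived from the normalized autocorrelation peak
at the pitch lag:

    HNR = 10 log10( r0 / (1 - r0) )        NHR = 1 - r0

where r0 is the autocorrelation peak height at the period lag. Cycles are
located by autocorrelation pitch tracking followed by refinement to the
waveform peak of each predicted cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import AudioSegment
from .errors import (
    DegenerateSignalError,
    InsufficientCyclesError,
    InvalidArgumentError,
    InvalidCycleError,
    UnvoicedSignalError,
)

__all__ = [
    "PulseTrain",
    "HarmonicityResult",
    "detect_pulses",
    "jitter_abs",
    "jitter_rel",
    "shimmer_db",
    "shimmer_rel",
    "pitch_sd",
    "harmonicity",
]

# Minimum normalized-correlation peak for a frame to count as voiced.
VOICING_THRESHOLD = 0.45


@dataclass
class PulseTrain:
    """Detected (or generated) glottal cycles.

    ``pulse_times`` are strictly increasing cycle onsets (s); cycle i spans
    [t_i, t_{i+1}) with period T_i = t_{i+1} - t_i and peak amplitude A_i.
    N = len(pulse_times) - 1 cycles.
    """

    pulse_times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if np.any(np.diff(self.pulse_times) <= 0):
            raise InvalidArgumentError("pulse_times must be strictly increasing")
        if len(self.amplitudes) != max(len(self.pulse_times) - 1, 0):
            raise InvalidArgumentError("need one amplitude per cycle (N = len(times)-1)")

    @property
    def periods(self) -> np.ndarray:
        return np.diff(self.pulse_times)

    @property
    def n_cycles(self) -> int:
        return len(self.pulse_times) - 1


@dataclass(frozen=True)
class HarmonicityResult:
    """Harmonicity of a segment, all fields derived from one averaged r0."""

    hnr_db: float
    nhr: float
    r0: float
    t0: float


def _norm_xcorr(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Pearson-normalized autocorrelation of x at the given positive lags.

    Each lag correlates x[:-l] with x[l:], both mean-removed, normalized by
    the product of their norms; bounded in [-1, 1] by Cauchy-Schwarz with no
    (1 - l/N) bias taper, which matters because the harmonicity measures
    live on the scale of r0 near 1.
    """
    n = len(x)
    out = np.empty(len(lags))
    for k, l in enumerate(lags):
        a = x[: n - l]
        b = x[l:]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
        out[k] = np.dot(a, b) / denom if denom > 0 else 0.0
    return out


def _frame_periods(
    x: np.ndarray,
    fs: float,
    fmin: float,
    fmax: float,
    frame_s: float = 0.040,
    overlap: float = 0.75,
):
    """Autocorrelation period estimate per frame.

    Returns (frame_centers_s, period_s, peak_r); unvoiced frames carry
    period NaN. Candidates at double/half the running median period are
    re-searched near the median (octave-error guard).
    """
    nwin = int(round(frame_s * fs))
    nstep = max(int(round(frame_s * (1.0 - overlap) * fs)), 1)
    lag_lo = max(int(np.floor(fs / fmax)), 2)
    lag_hi = min(int(np.ceil(fs / fmin)), nwin - 2)
    if lag_hi <= lag_lo:
        raise InvalidArgumentError("pitch search range empty at this sample rate")
    lags = np.arange(lag_lo, lag_hi + 1)

    centers, periods, peaks = [], [], []
    for start in range(0, len(x) - nwin + 1, nstep):
        seg = x[start : start + nwin]
        r = _norm_xcorr(seg, lags)
        k = int(np.argmax(r))
        # subharmonic guard: a lag of 2T correlates almost as well as T, so
        # among local maxima close to the global one, prefer the shortest lag
        if r[k] >= VOICING_THRESHOLD:
            local_max = np.where((r[1:-1] > r[:-2]) & (r[1:-1] >= r[2:]))[0] + 1
            credible = local_max[r[local_max] >= 0.87 * r[k]]
            if len(credible):
                k = int(credible[0])
        centers.append((start + nwin / 2) / fs)
        peaks.append(r[k])
        if r[k] >= VOICING_THRESHOLD:
            # parabolic refinement of the peak lag
            lag = lags[k]
            if 0 < k < len(r) - 1:
                denom = r[k - 1] - 2 * r[k] + r[k + 1]
                if denom < 0:
                    lag = lag + 0.5 * (r[k - 1] - r[k + 1]) / denom
            periods.append(lag / fs)
        else:
            periods.append(np.nan)

    centers = np.array(centers)
    periods = np.array(periods)
    peaks = np.array(peaks)

    voiced = ~np.isnan(periods)
    if voiced.sum() >= 3:
        med = np.median(periods[voiced])
        for i in np.where(voiced)[0]:
            ratio = periods[i] / med
            if not 0.7 <= ratio <= 1.43:  # likely octave error: re-search near median
                lo = max(int(med * fs * 0.77), lag_lo)
                hi = min(int(med * fs * 1.3), lag_hi)
                if hi > lo:
                    sub = np.arange(lo, hi + 1)
                    r = _norm_xcorr(x[int((centers[i] * fs) - nwin / 2) :][:nwin], sub)
                    k = int(np.argmax(r))
                    if r[k] >= VOICING_THRESHOLD:
                        periods[i] = sub[k] / fs
                        peaks[i] = r[k]
                    else:
                        periods[i] = np.nan
    return centers, periods, peaks


def detect_pulses(seg: AudioSegment, fmin: float = 75.0, fmax: float = 500.0) -> PulseTrain:
    """Locate glottal cycles by autocorrelation tracking + peak refinement.

    A period contour is estimated per 40 ms frame (75% overlap) over lags
    [1/fmax, 1/fmin]; starting from the strongest waveform peak, pulse times
    are marched forward and backward one predicted period at a time, each
    refined to the local waveform maximum; A_i is the peak absolute sample
    in cycle i. Cycles whose period deviates more than 30% from the local
    median are discarded.
    """
    if fmin >= fmax:
        raise InvalidArgumentError("fmin must be below fmax")
    x = seg.samples
    fs = seg.sample_rate
    if len(x) < 10.0 / fmin * fs:
        raise InvalidArgumentError(f"segment shorter than 10/fmin = {10 / fmin:.3f} s")

    centers, periods, peaks = _frame_periods(x, fs, fmin, fmax)
    voiced = ~np.isnan(periods)
    if voiced.sum() < max(2, len(periods) // 4):
        raise UnvoicedSignalError(
            f"only {int(voiced.sum())}/{len(periods)} frames voiced"
        )

    def local_period(t: float) -> float:
        return float(np.interp(t, centers[voiced], periods[voiced]))

    # polarity: track the dominant extreme so every cycle peak has equal sign
    anchor = int(np.argmax(np.abs(x)))
    sign = 1.0 if x[anchor] >= 0 else -1.0
    y = sign * x

    def refine(pred: int, period_n: float) -> int | None:
        lo = int(round(pred - 0.30 * period_n))
        hi = int(round(pred + 0.30 * period_n))
        if lo < 0 or hi >= len(y) or hi <= lo:
            return None
        return lo + int(np.argmax(y[lo : hi + 1]))

    marks = [anchor]
    cur = anchor
    while True:  # forward march
        p = local_period(cur / fs) * fs
        nxt = refine(int(round(cur + p)), p)
        if nxt is None or nxt <= cur:
            break
        marks.append(nxt)
        cur = nxt
    cur = anchor
    while True:  # backward march
        p = local_period(cur / fs) * fs
        prv = refine(int(round(cur - p)), p)
        if prv is None or prv >= cur:
            break
        marks.insert(0, prv)
        cur = prv

    marks = np.array(marks)
    times = marks / fs
    # discard cycles deviating > 30% from the local (9-point) median period
    while len(times) >= 3:
        T = np.diff(times)
        med = np.array([
            np.median(T[max(0, i - 4) : i + 5]) for i in range(len(T))
        ])
        bad = (np.abs(T - med) > 0.30 * med) | (1.0 / T < fmin * 0.9) | (1.0 / T > fmax * 1.1)
        if not np.any(bad):
            break
        # drop the later pulse of the worst offending cycle and re-check
        worst = int(np.argmax(np.where(bad, np.abs(T - med) / med, -np.inf)))
        times = np.delete(times, worst + 1)
    if len(times) < 3:
        raise UnvoicedSignalError("fewer than 2 clean cycles after screening")

    idx = np.round(times * fs).astype(int)
    # A_i: peak absolute amplitude of cycle i, measured in a window centered
    # on the pulse mark — a window spanning the whole cycle would sometimes
    # catch the build-up of the NEXT pulse and mix neighboring amplitudes
    half = max(int(0.2 * np.median(np.diff(idx))), 1)
    amps = np.array([
        np.max(np.abs(x[max(i - half, 0) : i + half + 1])) for i in idx[:-1]
    ])
    if np.any(amps <= 0):
        raise InvalidCycleError("cycle with zero peak amplitude")
    return PulseTrain(pulse_times=times, amplitudes=amps)


def _require_cycles(pt: PulseTrain, n: int = 2) -> None:
    if pt.n_cycles < n:
        raise InsufficientCyclesError(f"need >= {n} cycles, have {pt.n_cycles}")


def jitter_abs(pt: PulseTrain) -> float:
    """Mean absolute successive period difference, seconds."""
    _require_cycles(pt)
    return float(np.mean(np.abs(np.diff(pt.periods))))


def jitter_rel(pt: PulseTrain) -> float:
    """Absolute jitter normalized by the mean period (dimensionless)."""
    _require_cycles(pt)
    return jitter_abs(pt) / float(np.mean(pt.periods))


def shimmer_db(pt: PulseTrain) -> float:
    """Mean absolute successive amplitude ratio, dB: mean |20 log10(A_{i+1}/A_i)|."""
    _require_cycles(pt)
    if np.any(pt.amplitudes <= 0):
        raise InvalidCycleError("amplitudes must be positive")
    ratios = pt.amplitudes[1:] / pt.amplitudes[:-1]
    return float(np.mean(np.abs(20.0 * np.log10(ratios))))


def shimmer_rel(pt: PulseTrain) -> float:
    """Mean absolute successive amplitude difference over mean amplitude."""
    _require_cycles(pt)
    if np.any(pt.amplitudes <= 0):
        raise InvalidCycleError("amplitudes must be positive")
    return float(
        np.mean(np.abs(np.diff(pt.amplitudes))) / np.mean(pt.amplitudes)
    )


def pitch_sd(pt: PulseTrain) -> float:
    """Sample SD (n-1 denominator) of the instantaneous pitch 1/T_i, Hz."""
    _require_cycles(pt)
    return float(np.std(1.0 / pt.periods, ddof=1))


def harmonicity(
    seg: AudioSegment,
    pt: PulseTrain,
    frame_s: float = 0.040,
    overlap: float = 0.75,
) -> HarmonicityResult:
    """HNR/NHR from the normalized autocorrelation peak at the pitch lag.

    Per frame, the normalized autocorrelation is searched for its highest
    peak at a lag within +/-20% of the frame's local period; the peak
    heights r0 are averaged across frames *in the r0 domain* and converted
    once: HNR = 10 log10(r0/(1-r0)), NHR = 1 - r0. Averaging in dB would
    break the exact HNR/NHR consistency.
    """
    x = seg.samples
    fs = seg.sample_rate
    nwin = int(round(frame_s * fs))
    nstep = max(int(round(frame_s * (1.0 - overlap) * fs)), 1)
    times = pt.pulse_times
    periods = pt.periods
    mids = 0.5 * (times[:-1] + times[1:])

    r0s, t0s = [], []
    for start in range(0, len(x) - nwin + 1, nstep):
        center = (start + nwin / 2) / fs
        period = float(np.interp(center, mids, periods))
        lo = max(int(np.floor(period * 0.8 * fs)), 2)
        hi = min(int(np.ceil(period * 1.2 * fs)), nwin - 2)
        if hi <= lo:
            continue
        lags = np.arange(lo, hi + 1)
        r = _norm_xcorr(x[start : start + nwin], lags)
        k = int(np.argmax(r))
        if 0.0 < r[k] < 1.0:
            r0s.append(r[k])
            t0s.append(lags[k] / fs)
    if not r0s:
        raise DegenerateSignalError("no frame produced a usable autocorrelation peak")
    r0 = float(np.mean(r0s))
    return HarmonicityResult(
        hnr_db=10.0 * np.log10(r0 / (1.0 - r0)),
        nhr=1.0 - r0,
        r0=r0,
        t0=float(np.mean(t0s)),
    )
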