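"""Synthetic sustained-vowel generation with exact ground truth.

Source-filter synthesis: a train of glottal pulses (differentiated
Rosenberg pulses, one per cycle) with controlled cycle-period perturbation
(jitter) and cycle-amplitude perturbation (shimmer) excites a cascade of
second-order all-pole resonators (the vocal tract), after which band-limited
aperiodic noise is mixed in at a prescribed level and a slow gain drift is
applied. Every stochastic ingredient is drawn from a seeded generator and
the realized pulse sequence is returned alongside the waveform, so the
perturbation measures the analysis modules extract can be checked against
the values the generator actually produced.

Perturbation calibration is closed-form: with periods T_i = T0 (1 + s z_i)
for a fixed standardized draw z, the realized relative jitter equals
s a / (1 + s b) where a = mean|z_{i+1} - z_i| and b = mean z_i, which is
solved exactly for the scale s. The same identity calibrates shimmer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal

from .audio import AudioSegment, write_wav
from .errors import InvalidArgumentError
from .glottal import PulseTrain, jitter_abs, jitter_rel, shimmer_db, shimmer_rel

__all__ = [
    "SynthSpec",
    "SynthTruth",
    "SPEED_OF_SOUND_CM_S",
    "VOWEL_FORMANTS",
    "CLASS_PRESETS",
    "tube_formants",
    "make_pulse_train",
    "synthesize_vowel",
    "class_spec",
    "generate_dataset",
]

#: Speed of sound used for the closed-tube quarter-wavelength relation, cm/s.
SPEED_OF_SOUND_CM_S = 33_500.0

#: Typical adult formant targets (Hz) for the five sustained vowels.
VOWEL_FORMANTS = {
    "a": [730.0, 1090.0, 2440.0, 3400.0],
    "e": [530.0, 1840.0, 2480.0, 3520.0],
    "i": [300.0, 2300.0, 3000.0, 3800.0],
    "o": [500.0, 1000.0, 2400.0, 3300.0],
    "u": [330.0, 870.0, 2250.0, 3200.0],
}

#: Per-class perturbation presets. The disease class ("pd") has higher
#: period/amplitude perturbation, more aperiodic noise and larger intensity
#: drift than the control class ("control"), mirroring the direction of the
#: group differences reported for Parkinsonian sustained vowels; magnitudes
#: are chosen near the control/PD group means of those reports.
CLASS_PRESETS = {
    "control": dict(jitter_rel_target=0.005, shimmer_rel_target=0.045,
                    noise_db=-20.0, intensity_drift_db=1.5),
    "pd": dict(jitter_rel_target=0.008, shimmer_rel_target=0.058,
               noise_db=-16.0, intensity_drift_db=2.5),
}

_MIN_CYCLES = 40


@dataclass
class SynthSpec:
    """Parameters of one synthetic sustained vowel.

    Exactly one of ``tract_length_cm`` / ``formants_hz`` must be given; the
    former places resonances at the odd quarter-wavelength frequencies of a
    uniform closed tube of that length.
    """

    duration: float = 1.0
    sample_rate: float = 44_100.0
    f0: float = 120.0
    jitter_rel_target: float = 0.0
    shimmer_rel_target: float = 0.0
    noise_db: float = -60.0
    tract_length_cm: float | None = None
    formants_hz: list[float] | None = None
    bandwidths_hz: list[float] | None = None
    intensity_drift_db: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 75.0 <= self.f0 <= 500.0:
            raise InvalidArgumentError(f"f0 must lie in [75, 500] Hz, got {self.f0}")
        if self.duration < 0.6:
            raise InvalidArgumentError("duration must be >= 0.6 s")
        if self.duration * self.f0 < _MIN_CYCLES:
            raise InvalidArgumentError(
                f"duration x f0 = {self.duration * self.f0:.1f} < {_MIN_CYCLES} cycles"
            )
        for name in ("jitter_rel_target", "shimmer_rel_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.2:
                raise InvalidArgumentError(f"{name} must lie in [0, 0.2], got {v}")
        if (self.tract_length_cm is None) == (self.formants_hz is None):
            raise InvalidArgumentError(
                "exactly one of tract_length_cm / formants_hz must be set"
            )
        if self.tract_length_cm is not None and self.tract_length_cm <= 0:
            raise InvalidArgumentError("tract_length_cm must be positive")

    def resolved_formants(self) -> tuple[np.ndarray, np.ndarray]:
        """Formant frequencies and bandwidths (Hz) this spec implies."""
        if self.tract_length_cm is not None:
            freqs = np.array(tube_formants(self.tract_length_cm, 4))
        else:
            freqs = np.asarray(self.formants_hz, dtype=float)
        if self.bandwidths_hz is not None:
            bws = np.asarray(self.bandwidths_hz, dtype=float)
            if len(bws) != len(freqs):
                raise InvalidArgumentError("one bandwidth per formant required")
        else:
            bws = np.full(len(freqs), 80.0)  # typical speech formant bandwidth
        return freqs, bws


@dataclass
class SynthTruth:
    """Ground truth of an emitted vowel: the realized pulse sequence.

    ``pulse_times`` are the sample-grid times at which pulses were actually
    rendered; the perturbation values stored here are recomputed from that
    emitted sequence, so extracting them from ``pulse_times`` reproduces
    them exactly.
    """

    pulse_times: np.ndarray
    periods: np.ndarray
    amplitudes: np.ndarray
    formants_hz: np.ndarray
    bandwidths_hz: np.ndarray
    tract_length_cm: float | None
    f0: float
    jitter_abs: float
    jitter_rel: float
    shimmer_db: float
    shimmer_rel: float
    noise_db: float
    intensity_drift_db: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        payload = json.loads(Path(path).read_text())
        for k in ("pulse_times", "periods", "amplitudes", "formants_hz", "bandwidths_hz"):
            payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)


def tube_formants(tract_length_cm: float, n: int = 4) -> list[float]:
    """Resonances (Hz) of a uniform tube of length L closed at one end.

    F_i = (2i - 1) c / (4 L) with c = 33,500 cm/s: the odd quarter-wavelength
    series. Inverse of the apparent-vocal-tract-length relation, so feeding
    the result back through ``vtl_from_formants`` returns L at every index.
    """
    if tract_length_cm <= 0:
        raise InvalidArgumentError("tract_length_cm must be positive")
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    return [
        (2 * i - 1) * SPEED_OF_SOUND_CM_S / (4.0 * tract_length_cm)
        for i in range(1, n + 1)
    ]


def _truncated_normal(rng: np.random.Generator, size: int) -> np.ndarray:
    """Standard normal draws truncated at +/-3 (redraw outside)."""
    z = rng.standard_normal(size)
    bad = np.abs(z) > 3.0
    while np.any(bad):
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > 3.0
    return z


def _calibrated_scale(z: np.ndarray, target: float) -> float:
    """Scale s such that the sequence 1 + s z has relative perturbation `target`.

    Relative perturbation of x_i = 1 + s z_i is mean|dx| / mean x
    = s a / (1 + s b), a = mean|z_{i+1}-z_i|, b = mean z; solved for s.
    """
    if target == 0.0:
        return 0.0
    a = float(np.mean(np.abs(np.diff(z))))
    b = float(np.mean(z))
    denom = a - target * b
    if denom <= 0:  # pathological draw; cannot realize the target
        raise InvalidArgumentError("cannot calibrate perturbation for this draw")
    return target / denom


def make_pulse_train(spec: SynthSpec) -> PulseTrain:
    """Generate the glottal cycle sequence a :class:`SynthSpec` prescribes.

    Cycle periods are T_i = (1/f0)(1 + s z_i) with z a truncated standard
    normal draw and s calibrated so the relative jitter of the emitted
    sequence equals ``jitter_rel_target`` exactly; amplitudes analogous for
    shimmer. Deterministic under a fixed seed. Times are continuous
    (unquantized); :func:`synthesize_vowel` snaps them to the sample grid
    and re-measures.
    """
    rng = np.random.default_rng(spec.seed)
    t0 = 1.0 / spec.f0
    n_cycles = int(np.floor((spec.duration - 0.04) * spec.f0))
    if n_cycles < _MIN_CYCLES:
        raise InvalidArgumentError(
            f"duration {spec.duration} s yields {n_cycles} < {_MIN_CYCLES} cycles"
        )
    zj = _truncated_normal(rng, n_cycles)
    za = _truncated_normal(rng, n_cycles)
    sj = _calibrated_scale(zj, spec.jitter_rel_target)
    sa = _calibrated_scale(za, spec.shimmer_rel_target)
    periods = t0 * (1.0 + sj * zj)
    amplitudes = 1.0 + sa * za
    pulse_times = 0.02 + np.concatenate([[0.0], np.cumsum(periods)])
    return PulseTrain(pulse_times=pulse_times, amplitudes=amplitudes)


def _rosenberg_derivative(period_s: float, fs: float, tn_s: float,
                          closure_sample: int) -> tuple[int, np.ndarray]:
    """One differentiated Rosenberg glottal pulse ending at a grid sample.

    Opening phase 40% of the cycle; closing time ``tn_s`` is a constant per
    recording (a fast, modal-voice closure of 0.08 of the mean cycle). The
    closure time must NOT scale with the individual cycle period: the
    closure spike's width sets the excitation level of the upper formants,
    so a period-proportional closure would convert period jitter into
    spurious waveform-amplitude shimmer.

    The analytic derivative of the Rosenberg flow pulse is evaluated at the
    exact global sample positions so that the closure spike — the pulse's
    peak-magnitude sample, normalized to -1 — lands precisely on
    ``closure_sample``, with no rounding-dependent shape changes. Returns
    (first_sample_index, samples).
    """
    tp = 0.40 * period_s
    tn = tn_s
    start_time = closure_sample / fs - (tp + tn)
    k0 = int(np.ceil(start_time * fs))
    t = np.arange(k0, closure_sample + 1) / fs - start_time
    d = np.where(
        t <= tp,
        0.5 * np.pi / tp * np.sin(np.pi * np.clip(t, 0.0, tp) / tp),
        -0.5 * np.pi / tn * np.sin(np.pi * (t - tp) / (2.0 * tn)),
    )
    return k0, d / (0.5 * np.pi / tn)


def synthesize_vowel(spec: SynthSpec) -> tuple[AudioSegment, SynthTruth]:
    """Render a sustained vowel and return it with its realized ground truth.

    The pulse train from :func:`make_pulse_train` is rendered on the sample
    grid (one differentiated Rosenberg pulse per cycle, scaled by A_i),
    filtered by the all-pole resonator cascade, mixed with 50 Hz-4 kHz
    band-limited Gaussian noise at ``noise_db`` relative to the harmonic
    part, multiplied by a slow dB-linear gain ramp spanning
    ``intensity_drift_db`` peak-to-peak, and peak-normalized to 0.95.
    """
    fs = spec.sample_rate
    freqs, bws = spec.resolved_formants()
    if np.any(freqs >= fs / 2):
        raise InvalidArgumentError(
            f"formants {freqs[freqs >= fs / 2]} Hz at or above Nyquist ({fs / 2} Hz)"
        )

    pt = make_pulse_train(spec)
    n = int(round(spec.duration * fs))

    # Snap pulse times to the sample grid; the quantized times are the truth.
    # Each pulse is rendered so its closure spike (the peak-magnitude sample,
    # the acoustic event a pulse marker tracks) lands exactly on the grid
    # time: anchoring the pulse ONSET instead would smear the period sequence,
    # because the closure instant sits a period-dependent fraction (~0.48 T_i)
    # after the onset.
    idx = np.round(pt.pulse_times * fs).astype(int)
    idx = idx[idx < n - 4]
    grid_times = idx / fs
    amps = pt.amplitudes[: len(idx) - 1]

    excitation = np.zeros(n)
    qperiods = np.diff(grid_times)
    tn_s = 0.08 / spec.f0  # constant closure time per recording
    for closure, period, amp in zip(idx[:-1], qperiods, amps):
        k0, pulse = _rosenberg_derivative(period, fs, tn_s, closure)
        a = max(k0, 0)
        stop = min(k0 + len(pulse), n)
        excitation[a:stop] += amp * pulse[a - k0 : stop - k0]

    harmonic = excitation
    for f, bw in zip(freqs, bws):  # Klatt-style cascade of digital resonators
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * f / fs
        b0 = 1.0 - 2.0 * r * np.cos(theta) + r * r
        harmonic = scipy.signal.lfilter([b0], [1.0, -2.0 * r * np.cos(theta), r * r], harmonic)

    # Aspiration-like noise: white Gaussian, band-limited to the 50 Hz-4 kHz
    # analysis band, then shaped by the same resonator cascade as the pulses
    # (noise is injected at the glottis, so it shares the tract's spectral
    # envelope); scaled to noise_db relative to the harmonic part.
    rng = np.random.default_rng(spec.seed + 1)  # independent of the pulse draws
    noise = rng.standard_normal(n)
    sos = scipy.signal.butter(4, [50.0, 4000.0], btype="bandpass", fs=fs, output="sos")
    noise = scipy.signal.sosfilt(sos, noise)
    for f, bw in zip(freqs, bws):
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * f / fs
        b0 = 1.0 - 2.0 * r * np.cos(theta) + r * r
        noise = scipy.signal.lfilter([b0], [1.0, -2.0 * r * np.cos(theta), r * r], noise)
    rms_h = np.sqrt(np.mean(harmonic**2))
    rms_n = np.sqrt(np.mean(noise**2))
    noise *= rms_h / rms_n * 10.0 ** (spec.noise_db / 20.0)

    y = harmonic + noise
    if spec.intensity_drift_db != 0.0:
        ramp_db = np.linspace(-0.5, 0.5, n) * spec.intensity_drift_db
        y = y * 10.0 ** (ramp_db / 20.0)
    y *= 0.95 / np.max(np.abs(y))

    emitted = PulseTrain(pulse_times=grid_times, amplitudes=amps)
    truth = SynthTruth(
        pulse_times=grid_times,
        periods=qperiods,
        amplitudes=amps,
        formants_hz=freqs,
        bandwidths_hz=bws,
        tract_length_cm=spec.tract_length_cm,
        f0=spec.f0,
        jitter_abs=jitter_abs(emitted),
        jitter_rel=jitter_rel(emitted),
        shimmer_db=shimmer_db(emitted),
        shimmer_rel=shimmer_rel(emitted),
        noise_db=spec.noise_db,
        intensity_drift_db=spec.intensity_drift_db,
        seed=spec.seed,
    )
    return AudioSegment(y, fs), truth


def class_spec(
    group: str,
    phoneme: str = "a",
    seed: int = 0,
    rng: np.random.Generator | None = None,
    **overrides,
) -> SynthSpec:
    """Build a SynthSpec from a per-class preset with subject-level variation.

    `group` is "control" or "pd". When `rng` is given, f0 and the preset
    perturbation levels receive mild lognormal subject-to-subject scatter so
    the two classes overlap the way real cohorts do.
    """
    if group not in CLASS_PRESETS:
        raise InvalidArgumentError(f"unknown group {group!r}; use 'control' or 'pd'")
    params = dict(CLASS_PRESETS[group])
    f0 = 120.0
    if rng is not None:
        f0 = float(np.clip(rng.normal(125.0, 20.0), 90.0, 220.0))
        for key in ("jitter_rel_target", "shimmer_rel_target"):
            params[key] = float(np.clip(params[key] * rng.lognormal(0.0, 0.35), 0.0, 0.2))
        params["noise_db"] = float(params["noise_db"] + rng.normal(0.0, 2.0))
        params["intensity_drift_db"] = float(
            max(params["intensity_drift_db"] * rng.lognormal(0.0, 0.3), 0.0)
        )
    params.update(overrides)
    params.setdefault("f0", f0)
    if "tract_length_cm" not in params and "formants_hz" not in params:
        params["formants_hz"] = list(VOWEL_FORMANTS[phoneme])
    return SynthSpec(seed=seed, **params)


def generate_dataset(
    out_dir,
    n_per_class: int,
    seed: int = 0,
    phonemes: tuple[str, ...] = ("a",),
    n_repetitions: int = 1,
    duration: float = 1.0,
    write_files: bool = True,
):
    """Generate a two-class cohort of synthetic sustained vowels.

    Layout: ``<out_dir>/<group>/<subject>/<phoneme>_<rep>.wav`` with a
    ``.truth.json`` sidecar per recording. Returns a manifest: list of dicts
    with group, subject, phoneme, repetition, path (None if not written),
    the AudioSegment and the SynthTruth.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    manifest = []
    for group in ("control", "pd"):
        for s in range(n_per_class):
            subject = f"{group[:2]}{s:03d}"
            subj_rng = np.random.default_rng(rng.integers(2**31))
            base_seed = int(subj_rng.integers(2**31))
            for phoneme in phonemes:
                spec0 = class_spec(group, phoneme, seed=base_seed, rng=subj_rng,
                                   duration=duration)
                for rep in range(n_repetitions):
                    spec = SynthSpec(**{**spec0.__dict__, "seed": base_seed + rep})
                    seg, truth = synthesize_vowel(spec)
                    path = None
                    if write_files and out_dir is not None:
                        d = out_dir / group / subject
                        d.mkdir(parents=True, exist_ok=True)
                        path = d / f"{phoneme}_{rep}.wav"
                        write_wav(path, seg)
                        truth.to_json(d / f"{phoneme}_{rep}.truth.json")
                    manifest.append(
                        dict(group=group, subject=subject, phoneme=phoneme,
                             repetition=rep, path=path, segment=seg, truth=truth)
                    )
    return manifest
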