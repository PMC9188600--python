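"""Audio container and WAV I/O.

An :class:`AudioSegment` is a mono waveform with a sample rate and the time
offset of its first sample within the source recording. All analysis modules
operate on this type; amplitudes are dimensionless in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .errors import InvalidArgumentError

__all__ = ["AudioSegment", "read_wav", "write_wav"]

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): 2**7}


@dataclass
class AudioSegment:
    """Mono waveform with sample rate (Hz) and origin time (s) in the source."""

    samples: np.ndarray
    sample_rate: float
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidArgumentError("AudioSegment requires a mono (1-D) waveform")
        if self.sample_rate <= 8000:
            raise InvalidArgumentError(
                f"sample_rate must exceed 8000 Hz, got {self.sample_rate}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample times (s), relative to the source recording."""
        return self.origin_time + np.arange(len(self.samples)) / self.sample_rate


def read_wav(path) -> AudioSegment:
    """Read a mono PCM/float WAV file into an :class:`AudioSegment`.

    Integer PCM (8/16/32-bit; 24-bit arrives as int32) is rescaled to
    [-1, 1); float data is taken as-is. Stereo files are rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise InvalidArgumentError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(np.float64)
    return AudioSegment(samples, float(rate))


def write_wav(path, seg: AudioSegment) -> None:
    """Write an :class:`AudioSegment` as 16-bit PCM mono WAV."""
    clipped = np.clip(seg.samples, -1.0, 1.0)
    pcm = np.clip(np.round(clipped * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(seg.sample_rate), pcm)
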