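"""Two-channel nasometer audio I/O.

A nasometer records the nose and mouth microphones on separate channels of
one synchronized stream.  This module reads, validates, resamples and writes
such recordings.  Amplitudes are always normalized to float in [-1, 1] on
read; integer PCM round-trips are bit-exact through :func:`write_dual_wav` /
:func:`read_dual_wav`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "DualChannelRecording",
    "DEFAULT_SAMPLE_RATE",
    "DEFAULT_CHANNEL_MAP",
    "read_dual_wav",
    "write_dual_wav",
    "resample",
    "ms_to_samples",
]

#: Default working sample rate in Hz.  Nasometer hardware rates vary by
#: vendor, so this is a configurable convention, not a device constant.
DEFAULT_SAMPLE_RATE = 44_100

#: Default channel convention: nose on channel 0, mouth on channel 1.
DEFAULT_CHANNEL_MAP: dict[str, int] = {"nose": 0, "mouth": 1}

_PCM_SCALE = {np.dtype("int16"): 2.0**15, np.dtype("int32"): 2.0**31}


class ChannelCountError(ValueError):
    """Raised when a WAV file does not contain exactly two channels."""


@dataclass(frozen=True)
class DualChannelRecording:
    """Synchronized nose/mouth waveforms with identity metadata.

    Parameters
    ----------
    nose, mouth : ndarray of float
        Amplitude samples in [-1, 1]; both channels have identical length.
    sample_rate : int
        Sampling rate in Hz, strictly positive.
    speaker_id, utterance_id : str
        Opaque identifiers used for grouping and provenance.
    """

    nose: np.ndarray
    mouth: np.ndarray
    sample_rate: int
    speaker_id: str = ""
    utterance_id: str = ""

    def __post_init__(self) -> None:
        nose = np.asarray(self.nose, dtype=np.float64)
        mouth = np.asarray(self.mouth, dtype=np.float64)
        object.__setattr__(self, "nose", nose)
        object.__setattr__(self, "mouth", mouth)
        if nose.ndim != 1 or mouth.ndim != 1:
            raise ValueError("channels must be one-dimensional sample arrays")
        if nose.shape != mouth.shape:
            raise ValueError(
                f"nose and mouth must have identical length "
                f"({nose.size} != {mouth.size})"
            )
        if int(self.sample_rate) <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def n_samples(self) -> int:
        return int(self.nose.size)

    @property
    def duration_ms(self) -> float:
        """Duration in milliseconds (non-negative)."""
        return 1000.0 * self.n_samples / self.sample_rate

    def swapped(self) -> "DualChannelRecording":
        """Return a copy with the nose and mouth channels exchanged."""
        return replace(self, nose=self.mouth, mouth=self.nose)

    def stack(self) -> np.ndarray:
        """Channels as a (2, n_samples) array, nose first."""
        return np.stack([self.nose, self.mouth])


def parse_channel_map(spec: str) -> dict[str, int]:
    """Parse a ``"nose=0,mouth=1"`` style channel-map string."""
    mapping: dict[str, int] = {}
    for part in spec.split(","):
        key, _, value = part.strip().partition("=")
        if key not in ("nose", "mouth"):
            raise ValueError(f"unknown channel name {key!r} in channel map")
        mapping[key] = int(value)
    if set(mapping) != {"nose", "mouth"} or len(set(mapping.values())) != 2:
        raise ValueError(f"channel map must assign nose and mouth to distinct channels: {spec!r}")
    return mapping


def read_dual_wav(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    speaker_id: str = "",
    utterance_id: str = "",
) -> DualChannelRecording:
    """Read a two-channel WAV file into a :class:`DualChannelRecording`.

    Integer PCM (16/24/32-bit) is rescaled to float in [-1, 1]; float WAVs
    are passed through.  ``channel_map`` assigns the named microphones to
    channel indices (default nose=0, mouth=1).

    Raises
    ------
    ChannelCountError
        If the file is mono or has more than two channels.
    """
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    rate, data = wavfile.read(str(path))
    if data.ndim != 2 or data.shape[1] != 2:
        n_ch = 1 if data.ndim == 1 else data.shape[1]
        raise ChannelCountError(
            f"{path}: expected a 2-channel WAV, found {n_ch} channel(s)"
        )
    data = np.asarray(data)
    if data.dtype in _PCM_SCALE:
        data = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    return DualChannelRecording(
        nose=data[:, channel_map["nose"]],
        mouth=data[:, channel_map["mouth"]],
        sample_rate=int(rate),
        speaker_id=speaker_id,
        utterance_id=utterance_id,
    )


def write_dual_wav(
    path: str | Path,
    rec: DualChannelRecording,
    channel_map: Mapping[str, int] | None = None,
    dtype: str = "int16",
) -> Path:
    """Write a recording to a two-channel WAV file.

    ``dtype`` may be ``"int16"`` (default, clipped/scaled PCM) or
    ``"float32"``.  The inverse of :func:`read_dual_wav` for int16 content
    that originated from int16 PCM.
    """
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    out = np.empty((rec.n_samples, 2), dtype=np.float64)
    out[:, channel_map["nose"]] = rec.nose
    out[:, channel_map["mouth"]] = rec.mouth
    if dtype == "int16":
        scaled = np.clip(out, -1.0, 1.0 - 1.0 / 2**15) * 2.0**15
        wavfile.write(str(path), rec.sample_rate, np.round(scaled).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(str(path), rec.sample_rate, out.astype(np.float32))
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    return Path(path)


def resample(rec: DualChannelRecording, target_rate: int) -> DualChannelRecording:
    """Resample both channels identically to ``target_rate`` Hz.

    Uses polyphase filtering; duration is preserved to within one sample
    period.  Returns the input unchanged when the rate already matches.
    """
    target_rate = int(target_rate)
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.sample_rate:
        return rec
    g = int(np.gcd(target_rate, rec.sample_rate))
    up, down = target_rate // g, rec.sample_rate // g
    return replace(
        rec,
        nose=resample_poly(rec.nose, up, down),
        mouth=resample_poly(rec.mouth, up, down),
        sample_rate=target_rate,
    )


def ms_to_samples(ms: float, sample_rate: int) -> int:
    """Convert milliseconds to a sample count, rounding half to even."""
    return int(np.rint(ms * sample_rate / 1000.0))
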