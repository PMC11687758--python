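"""MFCC feature stacks for dual-channel nasalance analysis.

Recordings are cut into overlapping analysis windows (250 ms long, one
starting every 100 ms by default).  Each window is rendered, per channel,
as a matrix of mel-frequency cepstral coefficients over short frames
(25 ms frames, 10 ms hop), optionally augmented with first and second
time-derivatives, and the two channels are stacked into a
``channels x coefficients x frames`` tensor (2 x 39 x 26 under defaults at
44.1 kHz).  These stacks are the input "two-color pictures" consumed by the
window classifier.

The cepstral front-end is implemented here with numpy/scipy: Hann-windowed
power spectra, a Slaney-style mel filterbank, a decibel floor, and an
orthonormal DCT-II, with delta features from a 9-frame linear regression
with edge replication.  All constants are pinned in :class:`FeatureConfig`
so stacks are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal.windows import hann

from .audio_io import DualChannelRecording, ms_to_samples

__all__ = [
    "FeatureConfig",
    "FeatureWindow",
    "segment_windows",
    "compute_feature_stack",
    "extract_feature_windows",
    "mfcc_matrix",
    "delta",
    "save_feature_windows",
    "load_feature_windows",
]

_DB_FLOOR = 1e-10  # power floor before log, keeps silent input finite


@dataclass(frozen=True)
class FeatureConfig:
    """Pinned constants of the feature front-end.

    ``window_ms``/``hop_ms`` control utterance segmentation; ``frame_ms``/
    ``frame_hop_ms`` the per-window cepstral framing.  With the defaults a
    250 ms window yields 26 centered frames and 13 static coefficients plus
    deltas and delta-deltas, i.e. a 2 x 39 x 26 stack.  Setting
    ``include_deltas=False`` with ``n_static=39`` gives the pure-static
    39-coefficient variant.
    """

    window_ms: float = 250.0
    hop_ms: float = 100.0
    frame_ms: float = 25.0
    frame_hop_ms: float = 10.0
    n_static: int = 13
    include_deltas: bool = True
    n_mel: int = 40
    centered_framing: bool = True
    delta_width: int = 9  # 9-frame regression window for deltas

    def __post_init__(self) -> None:
        if not (0 < self.hop_ms <= self.window_ms):
            raise ValueError("require 0 < hop_ms <= window_ms")
        if not (0 < self.frame_hop_ms <= self.frame_ms):
            raise ValueError("require 0 < frame_hop_ms <= frame_ms")
        if self.n_static <= 0 or self.n_mel < self.n_static:
            raise ValueError("require 0 < n_static <= n_mel")
        if self.delta_width < 3 or self.delta_width % 2 == 0:
            raise ValueError("delta_width must be an odd integer >= 3")

    @property
    def n_coeff(self) -> int:
        """Per-frame dimensionality: n_static x (1 + 2 if deltas)."""
        return self.n_static * (3 if self.include_deltas else 1)

    def n_frames(self, sample_rate: int) -> int:
        """Frame count of one window under centered framing."""
        win = ms_to_samples(self.window_ms, sample_rate)
        hop = ms_to_samples(self.frame_hop_ms, sample_rate)
        if self.centered_framing:
            return 1 + win // hop
        frame = ms_to_samples(self.frame_ms, sample_rate)
        return max(0, 1 + (win - frame) // hop)


@dataclass
class FeatureWindow:
    """One analysis window rendered as a feature stack with provenance."""

    stack: np.ndarray  # (channels, coefficients, frames)
    start_ms: float
    speaker_id: str = ""
    utterance_id: str = ""
    label: str = "unlabeled"  # {"oral", "nasal", "unlabeled"}

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=np.float64)
        if self.stack.ndim != 3:
            raise ValueError("stack must be channels x coefficients x frames")
        if not np.all(np.isfinite(self.stack)):
            raise ValueError("feature stack contains non-finite values")
        if self.label not in ("oral", "nasal", "unlabeled"):
            raise ValueError(f"invalid label {self.label!r}")


def segment_windows(
    rec: DualChannelRecording, cfg: FeatureConfig = FeatureConfig()
) -> list[tuple[float, np.ndarray]]:
    """Cut a recording into overlapping fixed-length window slices.

    Windows start at 0, hop_ms, 2*hop_ms, ...; each is exactly window_ms
    long and a trailing remainder shorter than window_ms is dropped, so the
    count is ``floor((duration_ms - window_ms)/hop_ms) + 1``.  A recording
    shorter than one window yields an empty list (not an error).

    Returns
    -------
    list of (start_ms, slice)
        ``slice`` is a (2, window_samples) array, nose channel first.
    """
    win = ms_to_samples(cfg.window_ms, rec.sample_rate)
    hop = ms_to_samples(cfg.hop_ms, rec.sample_rate)
    samples = rec.stack()
    out: list[tuple[float, np.ndarray]] = []
    start = 0
    while start + win <= rec.n_samples:
        out.append((1000.0 * start / rec.sample_rate, samples[:, start : start + win]))
        start += hop
    return out


def _frame_signal(x: np.ndarray, frame: int, hop: int, centered: bool) -> np.ndarray:
    """Slice a 1-D signal into (n_frames, frame) rows."""
    if centered:
        pad = frame // 2
        x = np.pad(x, pad, mode="reflect")
        n_frames = 1 + (x.size - 2 * pad) // hop
    else:
        n_frames = 1 + (x.size - frame) // hop
    idx = hop * np.arange(n_frames)[:, None] + np.arange(frame)[None, :]
    return x[idx]


def _slaney_mel(f: np.ndarray) -> np.ndarray:
    """Hz -> mel, Slaney formulation (linear below 1 kHz, log above)."""
    f = np.asarray(f, dtype=np.float64)
    f_min, f_sp = 0.0, 200.0 / 3
    mels = (f - f_min) / f_sp
    min_log_hz = 1000.0
    min_log_mel = (min_log_hz - f_min) / f_sp
    logstep = np.log(6.4) / 27.0
    log_t = f >= min_log_hz
    mels = np.where(log_t, min_log_mel + np.log(np.maximum(f, 1e-12) / min_log_hz) / logstep, mels)
    return mels


def _slaney_hz(mels: np.ndarray) -> np.ndarray:
    mels = np.asarray(mels, dtype=np.float64)
    f_min, f_sp = 0.0, 200.0 / 3
    freqs = f_min + f_sp * mels
    min_log_hz = 1000.0
    min_log_mel = (min_log_hz - f_min) / f_sp
    logstep = np.log(6.4) / 27.0
    log_t = mels >= min_log_mel
    return np.where(log_t, min_log_hz * np.exp(logstep * (mels - min_log_mel)), freqs)


def mel_filterbank(sample_rate: int, n_fft: int, n_mel: int) -> np.ndarray:
    """Slaney-normalized triangular mel filterbank, shape (n_mel, n_fft//2+1)."""
    fft_freqs = np.linspace(0.0, sample_rate / 2, n_fft // 2 + 1)
    mel_pts = np.linspace(
        _slaney_mel(0.0), _slaney_mel(sample_rate / 2.0), n_mel + 2
    )
    hz_pts = _slaney_hz(mel_pts)
    fdiff = np.diff(hz_pts)
    ramps = hz_pts[:, None] - fft_freqs[None, :]
    lower = -ramps[:-2] / fdiff[:-1, None]
    upper = ramps[2:] / fdiff[1:, None]
    weights = np.maximum(0.0, np.minimum(lower, upper))
    # Slaney area normalization: each triangle integrates to ~2/bandwidth
    enorm = 2.0 / (hz_pts[2 : n_mel + 2] - hz_pts[:n_mel])
    return weights * enorm[:, None]


def delta(coeffs: np.ndarray, width: int = 9) -> np.ndarray:
    """First-order regression delta along the frame (last) axis.

    ``width`` is the odd regression window length; edge frames are
    replicated before the regression so the output keeps the input shape.
    """
    half = width // 2
    k = np.arange(1, half + 1, dtype=np.float64)
    denom = 2.0 * np.sum(k**2)
    padded = np.pad(coeffs, [(0, 0)] * (coeffs.ndim - 1) + [(half, half)], mode="edge")
    out = np.zeros_like(coeffs, dtype=np.float64)
    n = coeffs.shape[-1]
    for i, w in enumerate(k, start=1):
        out += w * (padded[..., half + i : half + i + n] - padded[..., half - i : half - i + n])
    return out / denom


def mfcc_matrix(x: np.ndarray, sample_rate: int, cfg: FeatureConfig) -> np.ndarray:
    """Static mel-cepstral coefficients of one channel, shape (n_static, n_frames)."""
    frame = ms_to_samples(cfg.frame_ms, sample_rate)
    hop = ms_to_samples(cfg.frame_hop_ms, sample_rate)
    frames = _frame_signal(np.asarray(x, dtype=np.float64), frame, hop, cfg.centered_framing)
    win = hann(frame, sym=False)
    n_fft = int(2 ** np.ceil(np.log2(frame)))
    spec = np.abs(rfft(frames * win[None, :], n=n_fft, axis=1)) ** 2
    fbank = mel_filterbank(sample_rate, n_fft, cfg.n_mel)
    mel_power = spec @ fbank.T
    log_mel = 10.0 * np.log10(np.maximum(mel_power, _DB_FLOOR))
    cepstra = dct(log_mel, type=2, axis=1, norm="ortho")[:, : cfg.n_static]
    return cepstra.T


def compute_feature_stack(
    window: np.ndarray,
    sample_rate: int,
    cfg: FeatureConfig = FeatureConfig(),
    start_ms: float = 0.0,
    speaker_id: str = "",
    utterance_id: str = "",
    label: str = "unlabeled",
) -> FeatureWindow:
    """Render one dual-channel window slice as a feature stack.

    For each channel independently the static cepstra are computed and, if
    configured, delta and delta-delta rows appended; the channels are then
    stacked to shape ``(2, n_coeff, n_frames)``.  An all-zero slice is valid
    (the decibel floor keeps the stack finite).
    """
    window = np.asarray(window, dtype=np.float64)
    expected = ms_to_samples(cfg.window_ms, sample_rate)
    if window.ndim != 2 or window.shape[0] != 2:
        raise ValueError("window slice must have shape (2, n_samples)")
    if window.shape[1] != expected:
        raise ValueError(
            f"window slice must be {cfg.window_ms} ms = {expected} samples at "
            f"{sample_rate} Hz, got {window.shape[1]}"
        )
    planes = []
    for ch in range(2):
        static = mfcc_matrix(window[ch], sample_rate, cfg)
        if cfg.include_deltas:
            d1 = delta(static, cfg.delta_width)
            d2 = delta(d1, cfg.delta_width)
            planes.append(np.concatenate([static, d1, d2], axis=0))
        else:
            planes.append(static)
    return FeatureWindow(
        stack=np.stack(planes),
        start_ms=start_ms,
        speaker_id=speaker_id,
        utterance_id=utterance_id,
        label=label,
    )


def extract_feature_windows(
    rec: DualChannelRecording, cfg: FeatureConfig = FeatureConfig()
) -> list[FeatureWindow]:
    """Segment a recording and compute the feature stack of every window."""
    return [
        compute_feature_stack(
            slice_,
            rec.sample_rate,
            cfg,
            start_ms=start_ms,
            speaker_id=rec.speaker_id,
            utterance_id=rec.utterance_id,
        )
        for start_ms, slice_ in segment_windows(rec, cfg)
    ]


def save_feature_windows(windows: list[FeatureWindow], path: str | Path) -> Path:
    """Save stacks to an ``.npz`` tensor container plus a JSON sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), *[w.stack for w in windows])
    sidecar = [
        {
            "start_ms": w.start_ms,
            "speaker_id": w.speaker_id,
            "utterance_id": w.utterance_id,
            "label": w.label,
        }
        for w in windows
    ]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_feature_windows(path: str | Path) -> list[FeatureWindow]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        stacks = [npz[k] for k in npz.files]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return [FeatureWindow(stack=s, **meta) for s, meta in zip(stacks, sidecar)]
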