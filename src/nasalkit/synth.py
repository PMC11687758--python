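"""Synthetic dual-channel utterances with exact phone annotations.

The generator emulates the signal structure a nasometer separator plate
produces — and that nasalance methods exploit — without attempting
realistic speech synthesis:

* oral vowels: a harmonic voice source with a formant-like mid-frequency
  emphasis, dominant on the **mouth** channel, with only a small leakage
  gain on the nose channel;
* oral consonants: band-limited noise bursts on the mouth channel;
* nasal consonants: a low-frequency harmonic murmur with energy
  concentrated in a band that includes 450-750 Hz, dominant on the **nose**
  channel, with the mouth channel attenuated;
* vowel sections adjacent to nasal consonants are cross-faded toward the
  nasal recipe (schematic coarticulatory nasalization), mirroring the
  annotation rules used for training labels.

Each speaker has a nasality level in [0, 1]: the probability that any phone
slot is realized as a nasal consonant, so the realized nasal phone-time
fraction approximates the level.  Annotations tile each utterance exactly
and are correct by construction; a fixed seed yields bit-identical output.
Per-speaker fundamental frequency and gain variation keeps cross-validation
folds non-trivially different.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import DualChannelRecording, write_dual_wav, ms_to_samples
from .labeling import LabelingConfig, PhoneInterval, classify_phones, _nasalized_duration
from .textgrid import write_textgrid

__all__ = ["SynthConfig", "Cohort", "generate_utterance", "generate_speaker",
           "generate_cohort", "write_cohort"]

ORAL_CONSONANTS = ("p", "t", "k")
VOWELS = ("a", "e", "i", "o", "u")
NASAL_CONSONANTS = ("m", "n")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic cohort.

    ``nasality_levels`` gives one target nasal phone-time fraction per
    speaker; ``None`` spreads ``n_speakers`` levels evenly over
    [0, 0.9].  The acoustic recipe constants (leakage gains, murmur band,
    noise floor) control how separable nasal and oral windows are through
    the nose/mouth energy balance.
    """

    seed: int = 0
    n_speakers: int = 10
    utterances_per_speaker: int = 6
    nasality_levels: tuple[float, ...] | None = None
    phone_dur_range_ms: tuple[float, float] = (60.0, 160.0)
    target_speech_ms: float = 2500.0
    edge_silence_ms: float = 120.0
    sample_rate: int = 44_100
    f0_range_hz: tuple[float, float] = (170.0, 250.0)
    oral_leakage: float = 0.10       # oral energy reaching the nose channel
    nasal_mouth_leakage: float = 0.10  # nasal murmur reaching the mouth channel
    murmur_center_hz: float = 500.0  # murmur envelope peak; band covers 450-750 Hz
    noise_floor: float = 1e-3
    cohort_tag: str = "spk"

    def __post_init__(self) -> None:
        if self.n_speakers <= 0 or self.utterances_per_speaker <= 0:
            raise ValueError("speaker and utterance counts must be positive")
        lo, hi = self.phone_dur_range_ms
        if not 0 < lo < hi:
            raise ValueError("phone duration range must be positive and increasing")
        if not (0 < self.oral_leakage < 1 and 0 < self.nasal_mouth_leakage < 1):
            raise ValueError("leakage gains must lie in (0, 1)")
        if self.nasality_levels is not None:
            if len(self.nasality_levels) != self.n_speakers:
                raise ValueError("one nasality level per speaker required")
            if any(not 0 <= lv <= 1 for lv in self.nasality_levels):
                raise ValueError("nasality levels must lie in [0, 1]")

    def level_of(self, speaker_index: int) -> float:
        if self.nasality_levels is not None:
            return float(self.nasality_levels[speaker_index])
        if self.n_speakers == 1:
            return 0.45
        return 0.9 * speaker_index / (self.n_speakers - 1)


def _harmonic(t: np.ndarray, f0: float, center: float, width: float,
              nyquist: float, rng: np.random.Generator) -> np.ndarray:
    """Harmonic series with a Lorentzian spectral envelope around ``center``."""
    sig = np.zeros_like(t)
    h = 1
    while h * f0 < min(nyquist * 0.9, 5000.0):
        f = h * f0
        amp = 1.0 / (1.0 + ((f - center) / width) ** 2)
        if amp > 1e-3:
            sig += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        h += 1
    peak = np.max(np.abs(sig))
    return sig / peak if peak > 0 else sig


def _noise_band(n: int, sr: int, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    """White noise spectrally restricted to [lo, hi] Hz via FFT masking."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / sr)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    y = np.fft.irfft(spec, n=n)
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def _envelope(n: int, sr: int, ramp_ms: float = 5.0) -> np.ndarray:
    ramp = min(ms_to_samples(ramp_ms, sr), n // 2)
    env = np.ones(n)
    if ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return env


def _phone_channels(
    phone: str, n: int, cfg: SynthConfig, f0: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (mouth_oral, nose_oral, mouth_nasal, nose_nasal) recipes."""
    sr = cfg.sample_rate
    t = np.arange(n) / sr
    nyq = sr / 2
    # oral recipe of this phone
    if phone in VOWELS:
        centers = {"a": 900.0, "e": 1400.0, "i": 2200.0, "o": 700.0, "u": 500.0}
        oral = _harmonic(t, f0, centers[phone], 600.0, nyq, rng)
    else:  # oral consonant: broadband burst
        oral = 0.6 * _noise_band(n, sr, 1000.0, 4000.0, rng)
    mouth_oral = oral
    nose_oral = cfg.oral_leakage * oral
    # nasal recipe (murmur) at the same f0
    murmur = _harmonic(t, f0, cfg.murmur_center_hz, 300.0, nyq, rng)
    mouth_nasal = cfg.nasal_mouth_leakage * murmur
    nose_nasal = murmur
    return mouth_oral, nose_oral, mouth_nasal, nose_nasal


def generate_utterance(
    cfg: SynthConfig,
    nasality_level: float,
    rng: np.random.Generator,
    f0: float,
    gain: float,
    speaker_id: str = "",
    utterance_id: str = "",
) -> tuple[DualChannelRecording, list[PhoneInterval]]:
    """Synthesize one utterance and its exact phone annotation.

    Phone slots alternate consonant/vowel; each slot independently becomes a
    nasal consonant with probability ``nasality_level``.  Vowel sections in
    contact with nasal consonants are cross-faded toward the nasal recipe
    over the same durations the labeling rules nasalize.
    """
    if not 0.0 <= nasality_level <= 1.0:
        raise ValueError(f"nasality_level {nasality_level} outside [0, 1]")
    sr = cfg.sample_rate
    lo, hi = cfg.phone_dur_range_ms
    # draw the phone string and durations
    phones: list[str] = []
    durs: list[float] = []
    speech_ms, want_consonant = 0.0, True
    while speech_ms < cfg.target_speech_ms:
        if rng.uniform() < nasality_level:
            sym = NASAL_CONSONANTS[rng.integers(len(NASAL_CONSONANTS))]
        elif want_consonant:
            sym = ORAL_CONSONANTS[rng.integers(len(ORAL_CONSONANTS))]
        else:
            sym = VOWELS[rng.integers(len(VOWELS))]
        dur = float(rng.uniform(lo, hi))
        phones.append(sym)
        durs.append(dur)
        speech_ms += dur
        want_consonant = not want_consonant
    phones = [""] + phones + [""]
    durs = [cfg.edge_silence_ms] + durs + [cfg.edge_silence_ms]

    # exact annotation tiling the utterance (sample-aligned boundaries)
    bounds_samples = np.concatenate([[0], np.cumsum(
        [ms_to_samples(d, sr) for d in durs])])
    intervals = [
        PhoneInterval(label=phones[k],
                      start_ms=1000.0 * bounds_samples[k] / sr,
                      end_ms=1000.0 * bounds_samples[k + 1] / sr)
        for k in range(len(phones))
    ]
    classified = classify_phones(intervals)

    n_total = int(bounds_samples[-1])
    mouth = np.zeros(n_total)
    nose = np.zeros(n_total)
    lab_cfg = LabelingConfig()
    for k, iv in enumerate(classified):
        a, b = int(bounds_samples[k]), int(bounds_samples[k + 1])
        n = b - a
        if n == 0 or iv.phone_class == "silence":
            continue
        phone_f0 = f0 * (1.0 + 0.02 * rng.standard_normal())
        m_o, n_o, m_n, n_n = _phone_channels(iv.label, n, cfg, phone_f0, rng)
        # nasal mixing weight over the phone
        w = np.zeros(n)
        if iv.phone_class == "nasal_consonant":
            w[:] = 1.0
        elif iv.phone_class == "vowel":
            d_prime = _nasalized_duration(iv.duration_ms, lab_cfg)
            n_nasal = min(ms_to_samples(d_prime, sr), n)
            prev_nasal = k > 0 and classified[k - 1].phone_class == "nasal_consonant"
            next_nasal = (k + 1 < len(classified)
                          and classified[k + 1].phone_class == "nasal_consonant")
            if prev_nasal:
                w[:n_nasal] = 1.0
            if next_nasal:
                w[n - n_nasal:] = 1.0
        env = gain * _envelope(n, sr)
        mouth[a:b] = env * ((1 - w) * m_o + w * m_n)
        nose[a:b] = env * ((1 - w) * n_o + w * n_n)

    mouth += cfg.noise_floor * rng.standard_normal(n_total)
    nose += cfg.noise_floor * rng.standard_normal(n_total)
    peak = max(np.max(np.abs(mouth)), np.max(np.abs(nose)))
    if peak > 1.0:
        mouth, nose = mouth / peak, nose / peak
    rec = DualChannelRecording(nose=nose, mouth=mouth, sample_rate=sr,
                              speaker_id=speaker_id, utterance_id=utterance_id)
    return rec, intervals


def generate_speaker(
    cfg: SynthConfig, speaker_index: int
) -> list[tuple[DualChannelRecording, list[PhoneInterval]]]:
    """All utterances of one speaker, deterministically from the seed."""
    voice_rng = np.random.default_rng((cfg.seed, speaker_index, 0x5BEA))
    f0 = float(voice_rng.uniform(*cfg.f0_range_hz))
    gain = float(voice_rng.uniform(0.6, 0.95))
    level = cfg.level_of(speaker_index)
    speaker_id = f"{cfg.cohort_tag}{speaker_index:02d}"
    out = []
    for u in range(cfg.utterances_per_speaker):
        rng = np.random.default_rng((cfg.seed, speaker_index, u, 0xA0D10))
        rec, ivs = generate_utterance(
            cfg, level, rng, f0, gain,
            speaker_id=speaker_id, utterance_id=f"{speaker_id}_u{u:02d}",
        )
        out.append((rec, ivs))
    return out


@dataclass
class Cohort:
    """A generated cohort: recordings, annotations and the speaker manifest."""

    utterances: list[tuple[DualChannelRecording, list[PhoneInterval]]]
    manifest: pd.DataFrame  # speaker_id, nasality_level, n_utterances

    @property
    def speaker_levels(self) -> dict[str, float]:
        return dict(zip(self.manifest["speaker_id"], self.manifest["nasality_level"]))


def generate_cohort(cfg: SynthConfig) -> Cohort:
    """Generate every speaker of a cohort with its ground-truth manifest.

    The manifest records each speaker's target nasality level, which
    establishes a known ranking for parameter-recovery tests.
    """
    utterances = []
    rows = []
    for s in range(cfg.n_speakers):
        per_speaker = generate_speaker(cfg, s)
        utterances.extend(per_speaker)
        rows.append({
            "speaker_id": per_speaker[0][0].speaker_id,
            "nasality_level": cfg.level_of(s),
            "n_utterances": len(per_speaker),
        })
    return Cohort(utterances=utterances, manifest=pd.DataFrame(rows))


def write_cohort(cfg: SynthConfig, out_dir: str | Path,
                 overwrite: bool = False) -> Path:
    """Write a cohort as WAV + TextGrid pairs plus a manifest CSV."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)
    for rec, intervals in cohort.utterances:
        write_dual_wav(out_dir / f"{rec.utterance_id}.wav", rec)
        write_textgrid(out_dir / f"{rec.utterance_id}.TextGrid", intervals)
    cohort.manifest.to_csv(manifest_path, index=False)
    return out_dir
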