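"""Synthetic two-class motor-imagery EEG with lateralized ERD.

Generates multi-subject recordings carrying the structure the decoding
pipeline assumes: ongoing mu (~10 Hz) and beta (~20 Hz) sensorimotor
rhythms at two lateral motor sources over 1/f^alpha background noise, with
event-related desynchronization (ERD) — a *multiplicative amplitude
attenuation* of the contralateral source's rhythms — during each imagery
window.  Imagining the left hand attenuates the right-hemisphere source and
vice versa; this lateralized band-power asymmetry is exactly what spatial
filters (the depthwise convolution, or CSP) can pick up.

The trial timeline mirrors a cue-paced experiment: a rest period, a cue
marking imagery onset, a fixed imagery window, and an inter-trial gap.
Channel topography is simplified to a 1-D channel axis with Gaussian
spatial spread around each source; volume conduction and artifacts are not
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .io import RawRecording, TrialTensor, epoch_trials
from .preprocessing import FilterSpec, preprocess

#: canonical class order: label 0 = left-hand imagery, 1 = right-hand imagery
CLASS_NAMES = ["left", "right"]


@dataclass(frozen=True)
class SynthConfig:
    """Generative parameters of the ERD simulator.

    ``erd_depth`` is the fractional amplitude reduction of the contralateral
    source during imagery (0 = no effect, 1 = complete suppression);
    ``snr_db`` sets rhythm-to-background power at the source channel during
    rest.  Defaults emulate a 64-channel, 1000 Hz, 60-trial session with
    3-second imagery epochs.
    """

    n_channels: int = 64
    fs: float = 1000.0
    trial_len_s: float = 3.0
    n_trials: int = 60
    rest_s: float = 4.0
    gap_s: float = 2.0
    mu_hz: float = 10.0
    beta_hz: float = 20.0
    erd_depth: float = 0.6
    snr_db: float = 6.0
    noise_exponent: float = 1.0
    subject_jitter: float = 0.1
    noise_rms_uv: float = 10.0
    peak_uv: float = 50.0
    spatial_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth <= 1:
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if self.n_trials % 2:
            raise ValueError("n_trials must be even (balanced two-class design)")
        if self.n_channels < 2:
            raise ValueError("need at least two channels for two lateral sources")
        for name in ("fs", "trial_len_s", "rest_s", "noise_rms_uv", "peak_uv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def left_motor_channel(self) -> int:
        """Left-hemisphere motor source (C3-like position on the channel axis)."""
        return self.n_channels // 3

    @property
    def right_motor_channel(self) -> int:
        """Right-hemisphere motor source (C4-like)."""
        return 2 * self.n_channels // 3

    @property
    def trial_period_s(self) -> float:
        return self.rest_s + self.trial_len_s + self.gap_s


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, alpha: float) -> np.ndarray:
    """Per-channel 1/f^alpha noise, unit variance."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-alpha / 2.0)
    shaping[0] = 0.0  # no DC drift
    spectrum = (rng.standard_normal((n_channels, freqs.size))
                + 1j * rng.standard_normal((n_channels, freqs.size))) * shaping
    noise = np.fft.irfft(spectrum, n=n_samples, axis=1)
    noise /= noise.std(axis=1, keepdims=True)
    return noise


def _slow_envelope(rng: np.random.Generator, n_samples: int, fs: float,
                   cutoff_hz: float = 1.0, depth: float = 0.3) -> np.ndarray:
    """Positive slow amplitude envelope with mean ~1 (waxing/waning rhythms)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spectrum = (rng.standard_normal(freqs.size)
                + 1j * rng.standard_normal(freqs.size))
    spectrum[freqs > cutoff_hz] = 0.0
    spectrum[0] = 0.0
    z = np.fft.irfft(spectrum, n=n_samples)
    std = z.std()
    if std > 0:
        z /= std
    return np.clip(1.0 + depth * z, 0.05, None)


def generate_subject(cfg: SynthConfig) -> RawRecording:
    """Generate one subject's continuous recording with cue events.

    Deterministic given ``cfg.seed``.  Event markers carry codes "left" /
    "right" at imagery onset, one per trial, in a seeded random balanced
    order.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n_per_trial = int(round(cfg.trial_period_s * fs))
    n_mi = int(round(cfg.trial_len_s * fs))
    n_rest = int(round(cfg.rest_s * fs))
    s_total = cfg.n_trials * n_per_trial

    # balanced, seeded-random class sequence
    labels = np.array([0, 1] * (cfg.n_trials // 2))
    rng.shuffle(labels)

    noise = _pink_noise(rng, cfg.n_channels, s_total, fs, cfg.noise_exponent)
    noise *= cfg.noise_rms_uv
    t = np.arange(s_total) / fs

    sources = {"left_src": cfg.left_motor_channel,
               "right_src": cfg.right_motor_channel}
    # ERD gain per source: attenuate during imagery of the *contralateral* hand
    erd_for_source = {"left_src": 1, "right_src": 0}  # source <- class label
    signal = noise
    chan_idx = np.arange(cfg.n_channels)

    p_noise = cfg.noise_rms_uv**2
    p_rhythm = p_noise * 10.0 ** (cfg.snr_db / 10.0)

    for src_name, src_ch in sources.items():
        osc = np.zeros(s_total)
        for f_hz, power_share in ((cfg.mu_hz, 2 / 3), (cfg.beta_hz, 1 / 3)):
            env = _slow_envelope(rng, s_total, fs)
            phase = rng.uniform(0, 2 * np.pi)
            carrier = np.sin(2 * np.pi * f_hz * t + phase) * env
            carrier *= np.sqrt(power_share * p_rhythm) / carrier.std()
            osc += carrier

        gain = np.ones(s_total)
        ramp_n = int(round(0.2 * fs))
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n))) if ramp_n else None
        for trial, lab in enumerate(labels):
            if lab != erd_for_source[src_name]:
                continue
            on = trial * n_per_trial + n_rest
            off = on + n_mi
            gain[on:off] = 1.0 - cfg.erd_depth
            if ramp_n and on - 0 >= 0:
                gain[max(0, on - ramp_n):on] = 1.0 - cfg.erd_depth * ramp[:min(ramp_n, on)]
                tail = gain[off:off + ramp_n]
                tail[:] = 1.0 - cfg.erd_depth * ramp[::-1][:tail.size]
        osc = osc * gain
        spread = np.exp(-((chan_idx - src_ch) ** 2) / (2 * cfg.spatial_sigma**2))
        signal = signal + spread[:, None] * osc[None, :]

    # scale to a realistic EDF amplitude range (~ +-peak_uv microvolts)
    signal *= cfg.peak_uv / np.max(np.abs(signal))

    events = [
        (trial * n_per_trial + n_rest, CLASS_NAMES[int(lab)])
        for trial, lab in enumerate(labels)
    ]
    names = [f"ch{i:02d}" for i in range(cfg.n_channels)]
    return RawRecording(signal=signal, fs=fs, channel_names=names,
                        event_markers=events)


def make_subject_trials(cfg: SynthConfig, target_fs: float = 100.0,
                        filter_spec: FilterSpec | None = None) -> TrialTensor:
    """Generate, band-pass, decimate, and epoch one subject end-to-end."""
    rec = generate_subject(cfg)
    rec = preprocess(rec, filter_spec, target_fs)
    return epoch_trials(rec, {"left": 0, "right": 1},
                        epoch_len_s=cfg.trial_len_s, class_names=CLASS_NAMES)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectSpec:
    """A resolved per-subject configuration within a cohort."""

    subject_id: str
    role: Literal["source", "target"]
    cohort: Literal["easy", "hard"]
    config: SynthConfig

    def generate(self) -> RawRecording:
        return generate_subject(self.config)

    def trials(self, target_fs: float = 100.0) -> TrialTensor:
        return make_subject_trials(self.config, target_fs=target_fs)


def _jittered(cfg: SynthConfig, rng: np.random.Generator, hard: bool,
              seed: int) -> SynthConfig:
    erd = cfg.erd_depth * (0.5 if hard else 1.0)
    snr = cfg.snr_db - (6.0 if hard else 0.0)
    j = cfg.subject_jitter
    erd = float(np.clip(erd * rng.uniform(1 - j, 1 + j), 0.0, 1.0))
    snr = float(snr + rng.uniform(-10 * j, 10 * j))
    return replace(cfg, erd_depth=erd, snr_db=snr, seed=seed)


def generate_cohort(
    n_source_subjects: int,
    n_target_subjects: int,
    cfg: SynthConfig | None = None,
    difficulty_profile: Literal["easy", "hard"] = "easy",
) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Draw per-subject parameters for a source corpus and target subjects.

    Source subjects always follow the "easy" (healthy-like) profile; the
    ``difficulty_profile`` applies to targets.  "hard" halves the ERD depth
    and lowers SNR by 6 dB, emulating the less stable recordings of
    patients.  Returns lazy subject specs plus a manifest table.
    """
    if n_source_subjects < 0 or n_target_subjects < 0 or \
            n_source_subjects + n_target_subjects < 1:
        raise ValueError("cohort needs at least one subject")
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    specs: list[SubjectSpec] = []
    for i in range(n_source_subjects + n_target_subjects):
        is_target = i >= n_source_subjects
        hard = is_target and difficulty_profile == "hard"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_cfg = _jittered(cfg, rng, hard, sub_seed)
        specs.append(SubjectSpec(
            subject_id=f"S{i + 1:02d}",
            role="target" if is_target else "source",
            cohort="hard" if hard else "easy",
            config=sub_cfg,
        ))
    manifest = pd.DataFrame(
        [{"subject_id": s.subject_id, "role": s.role, "cohort": s.cohort,
          "seed": s.config.seed, "erd_depth": s.config.erd_depth,
          "snr_db": s.config.snr_db} for s in specs]
    )
    return specs, manifest


def pooled_source_trials(specs: list[SubjectSpec],
                         target_fs: float = 100.0) -> TrialTensor:
    """Concatenate all source subjects' preprocessed trials (pre-training set)."""
    parts = [s.trials(target_fs) for s in specs if s.role == "source"]
    if not parts:
        raise ValueError("no source subjects in cohort")
    return TrialTensor(
        data=np.concatenate([p.data for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        fs=parts[0].fs,
        class_names=list(parts[0].class_names),
    )


__all__ = [
    "CLASS_NAMES", "SynthConfig", "SubjectSpec",
    "generate_subject", "make_subject_trials",
    "generate_cohort", "pooled_source_trials",
]
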