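"""Seeded synthetic IMU cohorts with controllable fatigue signatures.

The generator emulates the statistical structure observed in labelled running
data: relative to the non-fatigued (NF) state, fatigued (F) strides show a
lower median acceleration magnitude, an inflated variance, and sporadic
outlier spikes.  Each stride is a two-harmonic periodic gait template per
channel, scaled by a per-participant amplitude (lognormal-free, simple
Gaussian random effect), attenuated by ``1 - delta`` under fatigue, with
Gaussian noise whose standard deviation inflates by ``1 + gamma`` under
fatigue and, with some probability, a single spike in a fatigued stride.

Setting ``delta = gamma = outlier_prob = 0`` yields the *null* cohort in
which F and NF strides are exchangeable — the control condition for
chance-level testing of every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigError
from .io import ImuRecording, StrideDataset, StrideWindow, CHANNEL_NAMES

#: channels emitted for synthetic strides (acceleration + gyro triads)
STRIDE_CHANNELS = ["ax", "ay", "az", "gx", "gy", "gz"]

# per-axis phase offsets (radians) so the triads are not collinear
_PHASES = {"ax": 0.0, "ay": 0.35, "az": 0.7, "gx": 1.2, "gy": 1.55, "gz": 1.9}
# relative channel gains: gyro channels weaker than acceleration
_GAINS = {"ax": 1.0, "ay": 0.8, "az": 0.9, "gx": 0.5, "gy": 0.45, "gz": 0.4}


@dataclass
class SyntheticConfig:
    """Cohort-generator settings.

    ``amplitude_attenuation`` (δ) multiplies fatigued-stride amplitude by
    ``1 - δ``; ``variance_inflation`` (γ) multiplies fatigued-stride noise sd
    by ``1 + γ``; fatigued strides additionally receive one spike of
    ``outlier_scale`` times the participant amplitude with probability
    ``outlier_prob``.  Noise sd in the NF state is ``0.1 * base_amplitude``.
    """

    n_participants: int = 5
    strides_per_condition: int = 20
    L_stride: int = 128
    sampling_rate_hz: float = 256.0
    base_amplitude: float = 1.0
    amplitude_attenuation: float = 0.3   # delta
    variance_inflation: float = 0.5      # gamma
    outlier_prob: float = 0.05
    outlier_scale: float = 3.0
    participant_sd: float = 0.05
    noise_sd_frac: float = 0.1           # sigma_NF = frac * base_amplitude
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.strides_per_condition < 1:
            raise ConfigError("strides_per_condition must be >= 1")
        if self.L_stride < 4:
            raise ConfigError("L_stride must be >= 4")
        if not self.sampling_rate_hz > 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if not self.base_amplitude > 0:
            raise ConfigError("base_amplitude must be positive")
        if not 0 <= self.amplitude_attenuation < 1:
            raise ConfigError("amplitude_attenuation must be in [0, 1)")
        if self.variance_inflation < 0:
            raise ConfigError("variance_inflation must be >= 0")
        if not 0 <= self.outlier_prob <= 1:
            raise ConfigError("outlier_prob must be in [0, 1]")
        if self.outlier_scale < 1:
            raise ConfigError("outlier_scale must be >= 1")
        if self.participant_sd < 0:
            raise ConfigError("participant_sd must be >= 0")
        return self

    @property
    def is_null(self) -> bool:
        return (self.amplitude_attenuation == 0 and self.variance_inflation == 0
                and self.outlier_prob == 0)


def gait_template(L: int, channel: str) -> np.ndarray:
    """Unit-amplitude two-harmonic gait template over one stride period."""
    t = np.arange(L) / L
    ph = _PHASES[channel]
    return _GAINS[channel] * (np.sin(2 * np.pi * t + ph)
                              + 0.5 * np.sin(4 * np.pi * t + ph))


def _participant_amplitudes(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal(cfg.n_participants)
    amp = cfg.base_amplitude * (1.0 + cfg.participant_sd * z)
    # a pathological draw must not flip the template sign
    return np.clip(amp, 0.05 * cfg.base_amplitude, None)


def generate_cohort(cfg: SyntheticConfig) -> StrideDataset:
    """Generate a labelled stride cohort; fully reproducible from cfg.seed.

    Each participant contributes ``strides_per_condition`` NF strides
    (label 0) followed by the same number of F strides (label 1).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    amps = _participant_amplitudes(cfg, rng)
    templates = np.stack([gait_template(cfg.L_stride, c) for c in STRIDE_CHANNELS])
    sigma_nf = cfg.noise_sd_frac * cfg.base_amplitude
    strides: list[StrideWindow] = []
    for p in range(cfg.n_participants):
        pid = f"P{p + 1:02d}"
        idx = 0
        for label in (0, 1):
            scale = amps[p] * (1.0 - cfg.amplitude_attenuation) if label else amps[p]
            sigma = sigma_nf * (1.0 + cfg.variance_inflation) if label else sigma_nf
            for _ in range(cfg.strides_per_condition):
                data = scale * templates + rng.normal(
                    0.0, sigma, size=templates.shape)
                if label == 1 and cfg.outlier_prob > 0 and rng.random() < cfg.outlier_prob:
                    ch = rng.integers(0, 3)  # spike on an acceleration axis
                    pos = rng.integers(0, cfg.L_stride)
                    data[ch, pos] += cfg.outlier_scale * amps[p] * rng.choice([-1.0, 1.0])
                strides.append(StrideWindow(pid, idx, label, data,
                                            cfg.sampling_rate_hz))
                idx += 1
    return StrideDataset(strides, list(STRIDE_CHANNELS), cfg.L_stride)


def generate_null_cohort(cfg: SyntheticConfig) -> StrideDataset:
    """Generate a no-effect cohort; F and NF strides are exchangeable."""
    cfg.validate()
    if not cfg.is_null:
        raise ConfigError(
            "null cohort requires amplitude_attenuation = variance_inflation "
            "= outlier_prob = 0"
        )
    return generate_cohort(cfg)


def null_config(**overrides) -> SyntheticConfig:
    """Convenience constructor for the null (no-effect) configuration."""
    overrides.update(amplitude_attenuation=0.0, variance_inflation=0.0,
                     outlier_prob=0.0)
    return SyntheticConfig(**overrides)


def generate_recording(n_periods: int,
                       period_s: float = 0.8,
                       sampling_rate_hz: float = 256.0,
                       amplitude: float = 1.0,
                       noise_sd: float = 0.05,
                       gravity: float = 9.81,
                       participant_id: str = "P01",
                       condition: str = "NF",
                       seed: int = 0) -> ImuRecording:
    """Generate a continuous 9-channel recording of repeated gait periods.

    Used to exercise stride segmentation: the template repeats exactly every
    ``period_s`` seconds, so the true period count is known.  The vertical
    axis (az) carries the gravity offset, so the acceleration composite
    magnitude shows one clean peak per gait cycle, as in real lumbar-mounted
    data.  Magnetometer channels carry a slowly varying orientation signal.
    """
    rng = np.random.default_rng(seed)
    n = int(round(n_periods * period_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    phase = t / period_s  # cycles
    channels: dict[str, np.ndarray] = {}
    for c in CHANNEL_NAMES:
        if c in _PHASES:
            ph = _PHASES[c]
            sig = _GAINS[c] * amplitude * (
                np.sin(2 * np.pi * phase + ph) + 0.5 * np.sin(4 * np.pi * phase + ph))
            if c == "az":
                sig = sig + gravity
        else:  # magnetometer: slow drift, no gait harmonic
            sig = 0.2 * amplitude * np.sin(2 * np.pi * t / (10 * period_s))
        channels[c] = sig + rng.normal(0.0, noise_sd, size=n)
    return ImuRecording(participant_id, condition, sampling_rate_hz, channels)
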