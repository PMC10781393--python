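"""Signal conditioning and stride segmentation.

The processing chain is: zero-phase Butterworth low-pass -> linear detrend ->
z-normalization -> peak-driven stride segmentation.  Filtering is applied
forward-backward (``scipy.signal.filtfilt``) so stride shapes are not
phase-shifted before template comparison; normalization comes last so
per-stride statistics are comparable across participants.

Segmentation detects peaks on the filtered acceleration composite magnitude
(Euclidean norm of the triad); each inter-peak interval is one stride,
linearly resampled to a fixed number of samples per channel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import ParameterError, SegmentationError
from .io import ImuRecording, StrideDataset, StrideWindow

logger = logging.getLogger(__name__)

_ACCEL = ("ax", "ay", "az")
_GYRO = ("gx", "gy", "gz")


@dataclass
class PreprocessConfig:
    lowpass_cutoff_hz: float = 20.0
    filter_order: int = 4
    detrend: bool = True
    znormalize: bool = True
    peak_min_distance_s: float = 0.4
    peak_min_prominence: float = 0.5
    L_stride: int = 128

    def validate(self) -> "PreprocessConfig":
        if not self.lowpass_cutoff_hz > 0:
            raise ParameterError("lowpass_cutoff_hz must be positive")
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")
        if self.L_stride < 4:
            raise ParameterError("L_stride must be >= 4")
        return self


def butterworth_lowpass(x: np.ndarray, rate_hz: float, cutoff_hz: float,
                        order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The effective magnitude response is the squared single-pass response, so
    attenuation above the cutoff is steeper than the one-pass design.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff_hz < rate_hz / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={rate_hz / 2}) Hz")
    if len(x) <= 3 * order:
        raise ParameterError(f"series too short ({len(x)}) for order {order}")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    # generous padding keeps filtfilt edge transients (and hence asymmetry on
    # symmetric inputs) at machine-precision level
    padlen = min(len(x) - 1, 30 * order)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def detrend_signal(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line (slope and intercept)."""
    return signal.detrend(np.asarray(x, dtype=float), type="linear")


def znormalize_signal(x: np.ndarray) -> np.ndarray:
    """Scale to zero mean and unit sample standard deviation (ddof=1).

    A constant series has no scale; it maps to all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ParameterError("z-normalization needs at least 2 samples")
    sd = np.std(x, ddof=1)
    if sd == 0:
        warnings.warn("z-normalizing a constant series; returning zeros",
                      stacklevel=2)
        logger.warning("degenerate input: constant series in znormalize_signal")
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def composite_magnitude(rec: ImuRecording, group: str = "accel") -> np.ndarray:
    """Per-sample Euclidean norm of the acceleration or gyro triad."""
    if group == "accel":
        triad = _ACCEL
    elif group == "gyro":
        triad = _GYRO
    else:
        raise ParameterError(f"group must be 'accel' or 'gyro', got {group!r}")
    stacked = np.vstack([rec.channels[c] for c in triad])
    return np.sqrt(np.sum(stacked ** 2, axis=0))


def resample_to_length(x: np.ndarray, L: int) -> np.ndarray:
    """Linear interpolation of a series onto L evenly spaced points."""
    x = np.asarray(x, dtype=float)
    if len(x) == L:
        return x.copy()
    old = np.linspace(0.0, 1.0, len(x))
    new = np.linspace(0.0, 1.0, L)
    return np.interp(new, old, x)


def preprocess_channel(x: np.ndarray, rate_hz: float,
                       cfg: PreprocessConfig) -> np.ndarray:
    """Filter -> detrend -> normalize one channel per the config flags."""
    y = butterworth_lowpass(x, rate_hz, cfg.lowpass_cutoff_hz, cfg.filter_order)
    if cfg.detrend:
        y = detrend_signal(y)
    if cfg.znormalize:
        y = znormalize_signal(y)
    return y


def segment_strides(rec: ImuRecording,
                    cfg: PreprocessConfig | None = None,
                    channels: list[str] | None = None) -> StrideDataset:
    """Segment a recording into fixed-length strides.

    Peaks are detected on the low-pass-filtered acceleration composite
    magnitude with the configured minimum inter-peak distance and prominence;
    each inter-peak interval becomes one stride, every channel linearly
    resampled to ``cfg.L_stride`` samples.  Strides inherit the recording's
    participant id and condition label (UNKNOWN maps to NF/0 with a warning).
    """
    cfg = (cfg or PreprocessConfig()).validate()
    channels = channels or ["ax", "ay", "az", "gx", "gy", "gz"]
    mag = composite_magnitude(rec, "accel")
    mag_f = butterworth_lowpass(mag, rec.sampling_rate_hz,
                                cfg.lowpass_cutoff_hz, cfg.filter_order)
    if np.std(mag_f) < 1e-12 * max(1.0, abs(float(np.mean(mag_f)))):
        raise SegmentationError("constant signal: found 0 peaks")
    peaks, _ = signal.find_peaks(
        mag_f,
        distance=max(1, int(round(cfg.peak_min_distance_s * rec.sampling_rate_hz))),
        prominence=cfg.peak_min_prominence * np.std(mag_f),
    )
    if len(peaks) < 2:
        raise SegmentationError(
            f"need >= 2 peaks to segment, found {len(peaks)}")
    if rec.condition == "UNKNOWN":
        logger.warning("recording %s has UNKNOWN condition; labelling strides 0",
                       rec.participant_id)
    label = 1 if rec.condition == "F" else 0
    processed = {c: preprocess_channel(rec.channels[c], rec.sampling_rate_hz, cfg)
                 for c in channels}
    strides = []
    for k, (a, b) in enumerate(zip(peaks[:-1], peaks[1:])):
        block = np.vstack([resample_to_length(processed[c][a:b], cfg.L_stride)
                           for c in channels])
        strides.append(StrideWindow(rec.participant_id, k, label, block,
                                    rec.sampling_rate_hz))
    return StrideDataset(strides, list(channels), cfg.L_stride)
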