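"""Per-stride feature extraction.

Three feature families per configured channel — time-domain statistics,
frequency-domain (power-spectral-density) descriptors, and sample entropy —
plus the signal magnitude area (SMA) of the acceleration triad.  Together
they cover summary location/spread, spectral content, and signal
irregularity, the signal aspects in which fatigue expresses itself in
lumbar-mounted IMU running data (lower median acceleration, wider spread,
sporadic outliers).

Conventions worth noting:

* ``variance`` is the population variance (ddof=0) so that the internal
  identity ``rms**2 == mean**2 + variance`` holds exactly.
* the PSD is a one-sided periodogram of the mean-removed channel, scaled so
  that the bins sum to the population variance (a discrete Parseval
  identity); ``spectral_entropy`` is the Shannon entropy (bits) of the
  normalized PSD.
* ``sample_entropy`` returns ``inf`` when no template of length m+1 repeats;
  dataset-level extraction flags and imputes such values with the
  finite-sample median of the column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ParameterError
from .io import StrideDataset

logger = logging.getLogger(__name__)

TIME_FEATURES = ("mean", "median", "variance", "rms", "min", "max", "iqr")
FREQ_FEATURES = ("total_power", "dominant_freq_hz", "spectral_entropy",
                 "band_power_low", "band_power_mid", "band_power_high")


@dataclass
class FeatureConfig:
    """Which channels to featurize and the entropy/band parameters."""

    channels: tuple[str, ...] = ("ax", "ay", "az")
    sampen_m: int = 2
    sampen_r: float = 0.2          # in units of the channel sd
    band_edges_hz: tuple[float, float] = (3.0, 10.0)
    include_sma: bool = True


def time_domain_features(x: np.ndarray) -> dict[str, float]:
    """Mean, median, population variance, RMS, min, max and IQR."""
    x = np.asarray(x, dtype=float)
    mean = float(np.mean(x))
    var = float(np.var(x))
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "mean": mean,
        "median": float(np.median(x)),
        "variance": var,
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "iqr": float(q75 - q25),
    }


def sma(accel_block: np.ndarray) -> float:
    """Signal magnitude area of a 3-channel acceleration block.

    SMA = (1/N) * sum_t (|ax| + |ay| + |az|); a gross activity-intensity
    measure, non-negative by construction.
    """
    block = np.atleast_2d(np.asarray(accel_block, dtype=float))
    if block.shape[0] != 3:
        raise ParameterError(f"SMA needs a 3-channel block, got {block.shape[0]}")
    return float(np.mean(np.sum(np.abs(block), axis=0)))


def power_spectral_density(x: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of the mean-removed series, bins summing to the
    population variance (discrete Parseval identity)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    X = np.fft.rfft(x - np.mean(x))
    p = np.abs(X) ** 2 / n ** 2
    # fold negative frequencies into the positive bins
    if n % 2 == 0:
        p[1:-1] *= 2.0
    else:
        p[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    return freqs, p


def frequency_features(x: np.ndarray, rate_hz: float,
                       band_edges_hz: tuple[float, float] = (3.0, 10.0)) -> dict[str, float]:
    """Total power, dominant frequency, spectral entropy, and band powers.

    Band powers integrate [0, lo), [lo, hi) and [hi, Nyquist] Hz; spectral
    entropy is in bits, bounded by log2(number of bins).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ParameterError("frequency features need >= 8 samples")
    freqs, p = power_spectral_density(x, rate_hz)
    total = float(np.sum(p))
    if total > 0:
        q = p / total
        nz = q[q > 0]
        entropy = float(-np.sum(nz * np.log2(nz)))
    else:
        entropy = 0.0
    lo, hi = band_edges_hz
    return {
        "total_power": total,
        "dominant_freq_hz": float(freqs[int(np.argmax(p))]),
        "spectral_entropy": entropy,
        "band_power_low": float(np.sum(p[(freqs >= 0) & (freqs < lo)])),
        "band_power_mid": float(np.sum(p[(freqs >= lo) & (freqs < hi)])),
        "band_power_high": float(np.sum(p[freqs >= hi])),
    }


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy -ln(A/B) with Chebyshev tolerance ``r`` in sd units.

    B counts pairs of length-m templates within tolerance, A the same at
    length m+1 (self-matches excluded).  Returns 0 for a constant series
    (every template matches) and ``inf`` when A or B is zero.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ParameterError(f"series length {n} too short for m={m}")
    if not r > 0:
        raise ParameterError("tolerance r must be positive")
    sd = np.std(x)
    tol = r * sd if sd > 0 else r
    counts = []
    for mm in (m, m + 1):
        # n - m templates at both lengths (the length-m list drops its last
        # template), so a constant series gives A = B and entropy 0
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        k = len(templ)
        # pairwise Chebyshev distances, upper triangle
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        iu = np.triu_indices(k, 1)
        counts.append(int(np.sum(d[iu] <= tol)))
    B, A = counts
    if A == 0 or B == 0:
        return float("inf")
    return float(-np.log(A / B))


def stride_feature_vector(data: np.ndarray, channel_names: list[str],
                          rate_hz: float, cfg: FeatureConfig) -> dict[str, float]:
    """Flat name -> value map for one stride matrix."""
    out: dict[str, float] = {}
    for ch in cfg.channels:
        xi = channel_names.index(ch)
        x = data[xi]
        for k, v in time_domain_features(x).items():
            out[f"{ch}__{k}"] = v
        for k, v in frequency_features(x, rate_hz, cfg.band_edges_hz).items():
            out[f"{ch}__{k}"] = v
        out[f"{ch}__sample_entropy"] = sample_entropy(x, cfg.sampen_m, cfg.sampen_r)
    if cfg.include_sma:
        rows = [channel_names.index(c) for c in ("ax", "ay", "az")]
        out["sma"] = sma(data[rows])
    return out


def extract_features(ds: StrideDataset,
                     cfg: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature matrix for a stride dataset, one row per stride.

    Index columns ``participant_id``, ``stride_index`` and ``label`` are
    carried through; non-finite features are imputed with the column median
    over finite values (and logged).
    """
    cfg = cfg or FeatureConfig()
    rows = []
    for s in ds.strides:
        row = {"participant_id": s.participant_id,
               "stride_index": s.stride_index, "label": s.label}
        row.update(stride_feature_vector(s.data, ds.channel_names,
                                         s.origin_rate_hz, cfg))
        rows.append(row)
    df = pd.DataFrame(rows)
    feat_cols = [c for c in df.columns
                 if c not in ("participant_id", "stride_index", "label")]
    for c in feat_cols:
        col = df[c].to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        if bad.any():
            fill = float(np.median(col[~bad])) if (~bad).any() else 0.0
            logger.warning("imputing %d non-finite values in feature %s with %g",
                           int(bad.sum()), c, fill)
            col[bad] = fill
            df[c] = col
    return df


def feature_matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an extract_features frame into (X, y, groups) arrays."""
    feat_cols = [c for c in df.columns
                 if c not in ("participant_id", "stride_index", "label")]
    return (df[feat_cols].to_numpy(dtype=float),
            df["label"].to_numpy(dtype=int),
            df["participant_id"].to_numpy(dtype=object))


class StrideFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer view of :func:`extract_features` for sklearn pipelines.

    ``fit`` memorizes column medians from the training strides so that
    non-finite features seen at transform time are imputed with *training*
    statistics.
    """

    def __init__(self, channels: tuple[str, ...] = ("ax", "ay", "az"),
                 sampen_m: int = 2, sampen_r: float = 0.2,
                 band_edges_hz: tuple[float, float] = (3.0, 10.0),
                 include_sma: bool = True):
        self.channels = channels
        self.sampen_m = sampen_m
        self.sampen_r = sampen_r
        self.band_edges_hz = band_edges_hz
        self.include_sma = include_sma

    def _config(self) -> FeatureConfig:
        return FeatureConfig(tuple(self.channels), self.sampen_m, self.sampen_r,
                             tuple(self.band_edges_hz), self.include_sma)

    def fit(self, ds: StrideDataset, y=None):
        df = extract_features(ds, self._config())
        self.feature_names_ = [c for c in df.columns
                               if c not in ("participant_id", "stride_index", "label")]
        self.medians_ = df[self.feature_names_].median().to_numpy(dtype=float)
        return self

    def transform(self, ds: StrideDataset) -> np.ndarray:
        cfg = self._config()
        rows = []
        for s in ds.strides:
            vec = stride_feature_vector(s.data, ds.channel_names,
                                        s.origin_rate_hz, cfg)
            rows.append([vec[name] for name in self.feature_names_])
        X = np.asarray(rows, dtype=float)
        bad = ~np.isfinite(X)
        if bad.any():
            X[bad] = np.broadcast_to(self.medians_, X.shape)[bad]
        return X
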