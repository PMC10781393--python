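"""DTW alignment and per-stride stamina scoring against a personal baseline.

Stamina is scored per stride as closeness to the athlete's own non-fatigued
(NF) movement pattern.  A baseline template is the pointwise median of the
athlete's NF strides; each stride's dynamic-time-warping (DTW) distance d to
the template is normalized by a personal scale kappa (the 95th percentile of
the NF strides' own distances) and mapped to

    Z = clip(1 - d / kappa, 0, 1),

so Z = 1 means indistinguishable from the NF baseline and Z = 0 means at
least as far from baseline as the worst NF stride.  Z is then categorized
into low / medium / high endurance bands.

DTW semantics (pinned so external implementations can be configured to
match): local cost |a_i - b_j|; step set {(1,0), (0,1), (1,1)} with unit
weights; boundary-anchored monotone paths; no path-length normalization of
the stored distance (normalization enters only through kappa).  An optional
Sakoe-Chiba band restricts |i - j|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import CalibrationError, ParameterError
from .io import StrideDataset, StrideWindow
from .preprocess import znormalize_signal

#: kappa floor per template sample, guards division by zero for perfectly
#: repeatable strides
KAPPA_FLOOR_PER_SAMPLE = 1e-6

CATEGORY_THRESHOLDS = (1.0 / 3.0, 2.0 / 3.0)


@dataclass
class DtwResult:
    distance: float
    path: list[tuple[int, int]]


def dtw_distance(a, b, band: int | None = None) -> DtwResult:
    """Exact DTW by dynamic programming, optionally Sakoe-Chiba banded.

    Returns the minimal cumulative |a_i - b_j| over monotone paths anchored
    at (0,0) and (n-1, m-1), plus one optimal path (ties broken diagonal
    first, then vertical).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ParameterError("DTW requires non-empty series")
    if band is not None:
        if band < abs(n - m):
            raise ParameterError(
                f"band {band} < |len(a)-len(b)| = {abs(n - m)}: no feasible path")
        if band < 0:
            raise ParameterError("band must be non-negative")
    D = np.full((n, m), np.inf)
    cost = np.abs(a[:, None] - b[None, :])
    for i in range(n):
        j_lo = 0 if band is None else max(0, i - band)
        j_hi = m if band is None else min(m, i + band + 1)
        for j in range(j_lo, j_hi):
            c = cost[i, j]
            if i == 0 and j == 0:
                D[i, j] = c
            else:
                best = np.inf
                if i > 0 and j > 0:
                    best = D[i - 1, j - 1]
                if i > 0:
                    best = min(best, D[i - 1, j])
                if j > 0:
                    best = min(best, D[i, j - 1])
                D[i, j] = c + best
    # backtrack, preferring the diagonal on ties
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            candidates.append((D[i - 1, j], (i - 1, j)))
        if j > 0:
            candidates.append((D[i, j - 1], (i, j - 1)))
        _, (i, j) = min(candidates, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return DtwResult(float(D[n - 1, m - 1]), path)


@dataclass
class BaselineTemplate:
    """Personal NF baseline: median stride matrix, the derived scoring
    series, and the distance normalizer kappa."""

    participant_id: str
    template: np.ndarray        # (n_channels, L) pointwise median of NF strides
    scoring_series: np.ndarray  # (L,) pointwise median of NF scoring series
    kappa: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise CalibrationError("kappa must be positive")
        if not np.isfinite(self.template).all():
            raise CalibrationError("template contains non-finite values")


@dataclass
class StaminaEstimate:
    participant_id: str
    stride_index: int
    label: int
    dtw_distance: float
    Z: float
    category: str


def scoring_series(stride: StrideWindow, channel_names: list[str],
                   channel: str = "accel_mag") -> np.ndarray:
    """The series a stride is scored on: by default the z-normalized
    acceleration composite magnitude; any single channel by name otherwise."""
    if channel == "accel_mag":
        rows = [channel_names.index(c) for c in ("ax", "ay", "az")]
        mag = np.sqrt(np.sum(stride.data[rows] ** 2, axis=0))
        return znormalize_signal(mag)
    return znormalize_signal(stride.data[channel_names.index(channel)])


def build_baseline_template(nf_strides: list[StrideWindow],
                            channel_names: list[str],
                            channel: str = "accel_mag",
                            band: int | None = None) -> BaselineTemplate:
    """Calibrate a participant's NF baseline template and scale kappa.

    The template is the pointwise median across the participant's NF
    strides; kappa is the 95th percentile of each NF stride's DTW distance
    to the template, floored at ``1e-6 * L_stride``.
    """
    if len(nf_strides) < 2:
        raise CalibrationError(
            f"need >= 2 non-fatigued strides to calibrate a baseline, "
            f"got {len(nf_strides)}")
    pids = {s.participant_id for s in nf_strides}
    if len(pids) != 1:
        raise CalibrationError(f"strides from multiple participants: {pids}")
    series = np.stack([scoring_series(s, channel_names, channel)
                       for s in nf_strides])
    template = np.median(np.stack([s.data for s in nf_strides]), axis=0)
    ref = np.median(series, axis=0)
    dists = [dtw_distance(s, ref, band=band).distance for s in series]
    floor = KAPPA_FLOOR_PER_SAMPLE * series.shape[1]
    kappa = max(float(np.percentile(dists, 95)), floor)
    return BaselineTemplate(pids.pop(), template, ref, kappa)


def categorize_stamina(Z: float,
                       thresholds: tuple[float, float] = CATEGORY_THRESHOLDS) -> str:
    """Band a stamina score: Z < t1 -> low; t1 <= Z < t2 -> medium;
    Z >= t2 -> high (intervals closed below, open above, top band closed)."""
    t1, t2 = thresholds
    if Z >= t2:
        return "high"
    if Z >= t1:
        return "medium"
    return "low"


def stamina_metric(stride: StrideWindow, template: BaselineTemplate,
                   channel_names: list[str], channel: str = "accel_mag",
                   band: int | None = None,
                   thresholds: tuple[float, float] = CATEGORY_THRESHOLDS) -> StaminaEstimate:
    """Score one stride: Z = clip(1 - d/kappa, 0, 1), d = DTW to baseline."""
    d = dtw_distance(scoring_series(stride, channel_names, channel),
                     template.scoring_series, band=band).distance
    Z = float(np.clip(1.0 - d / template.kappa, 0.0, 1.0))
    return StaminaEstimate(stride.participant_id, stride.stride_index,
                           stride.label, d, Z, categorize_stamina(Z, thresholds))


def validate_stamina(z_hat, z_true) -> dict[str, float]:
    """Agreement between estimated and true stamina: Pearson r plus
    Bland-Altman bias and 95% limits of agreement."""
    z_hat = np.asarray(z_hat, dtype=float)
    z_true = np.asarray(z_true, dtype=float)
    if len(z_hat) != len(z_true) or len(z_hat) < 3:
        raise ParameterError("need equal-length series of length >= 3")
    if np.std(z_hat) == 0 or np.std(z_true) == 0:
        raise ParameterError("correlation undefined for constant series")
    r = float(np.corrcoef(z_hat, z_true)[0, 1])
    diff = z_hat - z_true
    bias = float(np.mean(diff))
    half = 1.96 * float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    return {"pearson_r": r, "bland_altman_bias": bias,
            "bland_altman_limits": (bias - half, bias + half)}


def stamina_series(ds: StrideDataset, participant_id: str,
                   channel: str = "accel_mag", band: int | None = None,
                   thresholds: tuple[float, float] = CATEGORY_THRESHOLDS
                   ) -> tuple[list[StaminaEstimate], dict[str, float]]:
    """Score every stride of one participant against their NF baseline.

    Returns the ordered estimates and a summary (mean, sd, range of Z).
    """
    sub = ds.subset(participant_id=participant_id)
    if not len(sub):
        raise ParameterError(f"no strides for participant {participant_id!r}")
    nf = [s for s in sub.strides if s.label == 0]
    template = build_baseline_template(nf, ds.channel_names, channel, band)
    estimates = [stamina_metric(s, template, ds.channel_names, channel,
                                band, thresholds)
                 for s in sub.strides]
    zs = np.array([e.Z for e in estimates])
    summary = {"participant_id": participant_id, "n_strides": len(zs),
               "mean_Z": float(zs.mean()), "sd_Z": float(zs.std(ddof=1)) if len(zs) > 1 else 0.0,
               "min_Z": float(zs.min()), "max_Z": float(zs.max())}
    return estimates, summary


class StaminaScorer:
    """Estimator-style wrapper: fit builds per-participant NF baselines,
    transform scores strides to Z.

    Follows the fit/transform convention so it composes with pipeline-style
    code; fitted state lives in ``templates_``.
    """

    def __init__(self, channel: str = "accel_mag", band: int | None = None,
                 thresholds: tuple[float, float] = CATEGORY_THRESHOLDS):
        self.channel = channel
        self.band = band
        self.thresholds = thresholds

    def get_params(self, deep: bool = True) -> dict:
        return {"channel": self.channel, "band": self.band,
                "thresholds": self.thresholds}

    def set_params(self, **params) -> "StaminaScorer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ParameterError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, ds: StrideDataset, y=None) -> "StaminaScorer":
        self.channel_names_ = list(ds.channel_names)
        self.templates_ = {}
        errors = {}
        for pid in ds.participants():
            nf = [s for s in ds.strides if s.participant_id == pid and s.label == 0]
            try:
                self.templates_[pid] = build_baseline_template(
                    nf, ds.channel_names, self.channel, self.band)
            except CalibrationError as exc:
                errors[pid] = str(exc)
        self.calibration_errors_ = errors
        if not self.templates_:
            raise CalibrationError("no participant could be calibrated: "
                                   + "; ".join(errors.values()))
        return self

    def transform(self, ds: StrideDataset) -> list[StaminaEstimate]:
        out = []
        for s in ds.strides:
            if s.participant_id not in self.templates_:
                continue
            out.append(stamina_metric(s, self.templates_[s.participant_id],
                                      self.channel_names_, self.channel,
                                      self.band, self.thresholds))
        return out

    def fit_transform(self, ds: StrideDataset, y=None) -> list[StaminaEstimate]:
        return self.fit(ds).transform(ds)
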