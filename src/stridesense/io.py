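"""Data model and CSV readers/writers for IMU recordings and stride datasets.

A raw recording is a 9-channel matrix — triaxial acceleration (``ax..az``),
angular velocity (``gx..gz``) and magnetic orientation (``mx..mz``) — sampled
at a fixed rate (256 Hz for the public runners dataset this layout mirrors).
Condition labels mark whether the run was recorded before (``NF``) or after
(``F``) an exhaustive incremental shuttle-run protocol.

On disk a recording is a plain headered CSV (one sample per row) with a JSON
metadata sidecar; a stride dataset is one CSV row per (stride, channel) with
the resampled values in ``s0..s{L-1}`` columns.  Column names are mapped
through a user-supplied *dialect* so externally produced files (including the
public dataset layout) can be read without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, LabelError, ParseError

CHANNEL_NAMES: tuple[str, ...] = (
    "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz",
)
CONDITIONS = ("F", "NF", "UNKNOWN")

#: condition token -> binary label (1 = fatigued)
LABEL_MAP = {"F": 1, "NF": 0, "1": 1, "0": 0}


def parse_condition_label(token: object) -> int:
    """Map a condition token ('F'/'NF', '1'/'0', case-insensitive,
    whitespace-trimmed) to the binary fatigue label."""
    key = str(token).strip().upper()
    if key in ("1.0", "0.0"):  # numeric CSV round-trips
        key = key[0]
    if key not in LABEL_MAP:
        raise LabelError(f"unknown condition label token: {token!r}")
    return LABEL_MAP[key]


@dataclass
class ImuRecording:
    """One continuous 9-channel IMU recording with metadata.

    Parameters
    ----------
    participant_id : str
        Cohort identifier for the athlete.
    condition : str
        ``"F"`` (fatigued), ``"NF"`` (non-fatigued) or ``"UNKNOWN"``.
    sampling_rate_hz : float
        Samples per second; the reference dataset uses 256 Hz.
    channels : dict[str, np.ndarray]
        Ordered map of the 9 equal-length series.
    accel_unit : str
        Unit tag for the acceleration triad (``"m/s2"`` or ``"mg"``); stored,
        never implicitly converted.
    """

    participant_id: str
    condition: str
    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    accel_unit: str = "m/s2"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not self.sampling_rate_hz > 0:
            raise FormatError("sampling_rate_hz must be positive")
        if tuple(self.channels) != CHANNEL_NAMES:
            raise FormatError(
                f"channels must be exactly {CHANNEL_NAMES} in order, "
                f"got {tuple(self.channels)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1 or min(lengths) < 1:
            raise FormatError("all 9 channels must share one length >= 1")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(self.channels["ax"])

    def matrix(self) -> np.ndarray:
        """Channel-by-sample matrix in canonical channel order."""
        return np.vstack([self.channels[c] for c in CHANNEL_NAMES])


@dataclass
class StrideWindow:
    """A single segmented stride, resampled to a fixed length."""

    participant_id: str
    stride_index: int
    label: int  # 1 = fatigued
    data: np.ndarray  # (n_channels, L_stride)
    origin_rate_hz: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.label not in (0, 1):
            raise LabelError(f"stride label must be 0 or 1, got {self.label!r}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise FormatError("stride matrix must be non-empty")


@dataclass
class StrideDataset:
    """An ordered collection of strides sharing channel names and length."""

    strides: list[StrideWindow]
    channel_names: list[str]
    L_stride: int

    def __post_init__(self) -> None:
        n_ch = len(self.channel_names)
        for s in self.strides:
            if s.data.shape != (n_ch, self.L_stride):
                raise FormatError(
                    f"stride {s.participant_id}/{s.stride_index} has shape "
                    f"{s.data.shape}, expected ({n_ch}, {self.L_stride})"
                )
            if not s.participant_id:
                raise FormatError("participant_id must be non-empty")

    def __len__(self) -> int:
        return len(self.strides)

    def __iter__(self):
        return iter(self.strides)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.strides], dtype=int)

    @property
    def participant_ids(self) -> np.ndarray:
        return np.array([s.participant_id for s in self.strides], dtype=object)

    def tensor(self) -> np.ndarray:
        """(n_strides, n_channels, L_stride) array of the stride matrices."""
        return np.stack([s.data for s in self.strides])

    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.strides:
            seen.setdefault(s.participant_id, None)
        return list(seen)

    def stride_counts(self) -> dict[str, int]:
        """Per-participant stride counts."""
        counts: dict[str, int] = {}
        for s in self.strides:
            counts[s.participant_id] = counts.get(s.participant_id, 0) + 1
        return counts

    def subset(self, participant_id: str | None = None,
               label: int | None = None) -> "StrideDataset":
        kept = [
            s for s in self.strides
            if (participant_id is None or s.participant_id == participant_id)
            and (label is None or s.label == label)
        ]
        return StrideDataset(kept, self.channel_names, self.L_stride)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise FormatError(f"unknown channel {name!r}; have {self.channel_names}")


# ---------------------------------------------------------------------------
# recording CSV I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(rec: ImuRecording, path: str | Path) -> Path:
    """Write a recording as headered CSV (one sample per row) plus a JSON
    metadata sidecar ``<path>.meta.json``."""
    path = Path(path)
    df = pd.DataFrame({c: rec.channels[c] for c in CHANNEL_NAMES})
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "participant_id": rec.participant_id,
        "condition": rec.condition,
        "sampling_rate_hz": rec.sampling_rate_hz,
        "accel_unit": rec.accel_unit,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return path


def read_recording(path: str | Path,
                   dialect: Mapping[str, str] | None = None) -> ImuRecording:
    """Read a recording CSV (and its metadata sidecar if present).

    ``dialect`` maps canonical channel names (``ax`` ... ``mz``) to the column
    names actually used in the file; identity by default.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    colmap = {c: (dialect or {}).get(c, c) for c in CHANNEL_NAMES}
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"unparseable CSV {path}: {exc}") from exc
    for canon, col in colmap.items():
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} (channel {canon!r}) in {path}")
    channels = {}
    for canon, col in colmap.items():
        try:
            channels[canon] = df[col].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric value in column {col!r}: {exc}") from exc
    meta_path = _sidecar_path(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ImuRecording(
        participant_id=str(meta.get("participant_id", path.stem)),
        condition=str(meta.get("condition", "UNKNOWN")),
        sampling_rate_hz=float(meta.get("sampling_rate_hz", 256.0)),
        channels=channels,
        accel_unit=str(meta.get("accel_unit", "m/s2")),
    )


# ---------------------------------------------------------------------------
# stride dataset CSV I/O


def save_stride_dataset(ds: StrideDataset, path: str | Path) -> Path:
    """Write a stride dataset as CSV: one row per (stride, channel)."""
    path = Path(path)
    rows = []
    for s in ds.strides:
        for ci, ch in enumerate(ds.channel_names):
            row: dict[str, object] = {
                "participant_id": s.participant_id,
                "stride_index": s.stride_index,
                "label": "F" if s.label == 1 else "NF",
                "origin_rate_hz": s.origin_rate_hz,
                "channel": ch,
            }
            row.update({f"s{j}": s.data[ci, j] for j in range(ds.L_stride)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def load_stride_dataset(path: str | Path,
                        dialect: Mapping[str, str] | None = None) -> StrideDataset:
    """Load a stride dataset CSV written by :func:`save_stride_dataset` (or a
    compatible layout via ``dialect`` column-name remapping).

    Condition labels 'F'/'NF' (or 0/1) are mapped to binary with F -> 1.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    dialect = dialect or {}
    df = pd.read_csv(path)
    required = ["participant_id", "stride_index", "label", "channel"]
    for col in required:
        actual = dialect.get(col, col)
        if actual not in df.columns:
            raise FormatError(f"missing column {actual!r} in {path}")
        if actual != col:
            df = df.rename(columns={actual: col})
    sample_cols = sorted(
        (c for c in df.columns if c.startswith("s") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not sample_cols:
        raise FormatError(f"no sample columns s0..sN found in {path}")
    L = len(sample_cols)
    strides: list[StrideWindow] = []
    channel_names: list[str] | None = None
    for (pid, sidx), grp in df.groupby(["participant_id", "stride_index"], sort=False):
        chans = list(grp["channel"])
        if channel_names is None:
            channel_names = chans
        elif chans != channel_names:
            raise FormatError(
                f"stride {pid}/{sidx} channels {chans} differ from {channel_names}"
            )
        block = grp[sample_cols].to_numpy(dtype=float)
        if np.isnan(block).any():
            raise ParseError(
                f"stride {pid}/{sidx} has missing samples (expected {L} per channel)"
            )
        labels = {parse_condition_label(t) for t in grp["label"]}
        if len(labels) != 1:
            raise LabelError(f"stride {pid}/{sidx} has conflicting labels")
        rate = float(grp["origin_rate_hz"].iloc[0]) if "origin_rate_hz" in grp else 256.0
        strides.append(StrideWindow(str(pid), int(sidx), labels.pop(), block, rate))
    assert channel_names is not None, "empty stride dataset file"
    return StrideDataset(strides, channel_names, L)
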