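"""Reading, validating and gap-filling hand-keypoint tracks.

The pipeline consumes per-frame 2-D hand keypoints produced by a 21-landmark
hand-pose estimator (MediaPipe-style indexing).  Only four landmarks are
required downstream: the wrist (0), the thumb tip (4), the index-finger
metacarpophalangeal joint (5) and the index-finger tip (8).  Tables are read
in long format — one row per (frame, landmark) — identified either by the
numeric landmark index or by its canonical name.

Coordinates are treated as dimensionless: normalized image units and raw
pixels are both fine, because the downstream distance signal is palm-scaled
and therefore invariant to the absolute unit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyTrackError, FormatError

logger = logging.getLogger(__name__)

#: canonical landmark name -> 21-landmark hand-model index
LANDMARKS: Mapping[str, int] = {
    "wrist": 0,
    "thumb_tip": 4,
    "index_mcp": 5,
    "index_tip": 8,
}
_INDEX_TO_NAME = {v: k for k, v in LANDMARKS.items()}

#: frame rates accepted silently; anything else positive logs a notice
STANDARD_FPS = (25.0, 50.0)

#: default gap-fill horizon, expressed as a time span (s); see fill_gaps
DEFAULT_MAX_GAP_S = 0.2


@dataclass(frozen=True)
class GapReport:
    """Summary of missing-frame runs found (and possibly filled)."""

    n_missing_before: int = 0
    n_filled: int = 0
    n_trimmed: int = 0
    longest_run: int = 0


@dataclass
class HandTrack:
    """An ordered per-frame track of the four required hand landmarks.

    Each landmark array has shape (n_frames, 2); a frame missing a landmark
    holds NaN in that landmark's row.  ``frame_index`` is strictly increasing
    but need not be contiguous (frames dropped upstream leave holes in the
    index, not NaN rows).
    """

    frame_index: np.ndarray
    wrist: np.ndarray
    thumb_tip: np.ndarray
    index_mcp: np.ndarray
    index_tip: np.ndarray
    fps: float
    confidence: np.ndarray | None = None
    recording_id: str = ""
    subject_id: str = ""
    hand: str = "right"
    medication_state: str = "unknown"
    gap_report: GapReport = field(default_factory=GapReport)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        for name in LANDMARKS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.frame_index), 2):
                raise FormatError(
                    f"landmark '{name}' has shape {arr.shape}, expected "
                    f"({len(self.frame_index)}, 2)"
                )
            setattr(self, name, arr)
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if len(self.frame_index) >= 2 and np.any(np.diff(self.frame_index) <= 0):
            raise FormatError("frame_index must be strictly increasing")
        if self.fps not in STANDARD_FPS:
            logger.info(
                "non-standard frame rate %.3g fps for %r (25/50 expected)",
                self.fps,
                self.recording_id,
            )

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def missing_mask(self) -> np.ndarray:
        """True for frames where any required landmark coordinate is NaN."""
        stacked = np.column_stack(
            [getattr(self, name) for name in LANDMARKS]
        )
        return np.isnan(stacked).any(axis=1)

    @property
    def times_s(self) -> np.ndarray:
        """Timestamps of each frame in seconds (frame_index / fps)."""
        return self.frame_index / self.fps


_COLUMN_ALIASES = {
    "frame": "frame",
    "frame_index": "frame",
    "frame_idx": "frame",
    "landmark": "landmark",
    "keypoint": "landmark",
    "landmark_id": "landmark",
    "x": "x",
    "y": "y",
    "confidence": "confidence",
    "conf": "confidence",
    "score": "confidence",
}


def _canonical_landmark(value: object) -> str | None:
    """Map a landmark cell (name or numeric index) to a canonical name.

    Returns None for landmarks outside the four required ones (they are
    silently ignored — pose estimators emit all 21).
    """
    if isinstance(value, str):
        key = value.strip().lower()
        if key in LANDMARKS:
            return key
        try:
            idx = int(key)
        except ValueError:
            raise FormatError(f"unknown landmark identifier {value!r}")
        return _INDEX_TO_NAME.get(idx)
    try:
        idx = int(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise FormatError(f"unknown landmark identifier {value!r}")
    if not 0 <= idx <= 20:
        raise FormatError(f"landmark index {idx} outside the 21-landmark model")
    return _INDEX_TO_NAME.get(idx)


def _read_delimited(path) -> pd.DataFrame:
    """Comma/tab auto-detection with bit-exact float parsing."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_keypoint_table(
    path,
    fps: float,
    recording_id: str = "",
    subject_id: str = "",
    hand: str = "right",
    medication_state: str = "unknown",
    min_confidence: float | None = None,
) -> HandTrack:
    """Read a long-format keypoint table into a :class:`HandTrack`.

    The file is delimited text (comma or tab, auto-detected) with a header
    row containing at least ``frame``, ``landmark``, ``x``, ``y`` columns
    (``confidence`` optional).  Row order is irrelevant.  Frames lacking any
    of the four required landmarks — or, when ``min_confidence`` is set,
    having one below that threshold — are kept but flagged missing.
    """
    df = _read_delimited(path)
    cols = {}
    for col in df.columns:
        alias = _COLUMN_ALIASES.get(str(col).strip().lower())
        if alias is not None and alias not in cols:
            cols[alias] = col
    required = {"frame", "landmark", "x", "y"}
    if not required.issubset(cols):
        raise FormatError(
            f"keypoint table {path} missing columns "
            f"{sorted(required - set(cols))}; found {list(df.columns)}"
        )

    names = df[cols["landmark"]].map(_canonical_landmark)
    df = df.assign(_name=names).dropna(subset=["_name"])
    if df.empty:
        raise EmptyTrackError(f"no usable landmark rows in {path}")

    frames = np.sort(df[cols["frame"]].astype(int).unique())
    n = len(frames)
    pos = {f: i for i, f in enumerate(frames)}
    coords = {name: np.full((n, 2), np.nan) for name in LANDMARKS}
    conf = np.full(n, np.nan)
    has_conf = "confidence" in cols

    fidx = df[cols["frame"]].astype(int).map(pos).to_numpy()
    xs = df[cols["x"]].astype(float).to_numpy()
    ys = df[cols["y"]].astype(float).to_numpy()
    cs = df[cols["confidence"]].astype(float).to_numpy() if has_conf else None
    lnames = df["_name"].to_numpy()
    for name in LANDMARKS:
        sel = lnames == name
        coords[name][fidx[sel], 0] = xs[sel]
        coords[name][fidx[sel], 1] = ys[sel]
        if cs is not None:
            # keep the minimum confidence across a frame's landmarks
            for i, c in zip(fidx[sel], cs[sel]):
                conf[i] = c if math.isnan(conf[i]) else min(conf[i], c)

    if min_confidence is not None and cs is not None:
        low = conf < min_confidence
        for name in LANDMARKS:
            coords[name][low] = np.nan

    track = HandTrack(
        frame_index=frames,
        fps=fps,
        confidence=conf if has_conf else None,
        recording_id=recording_id,
        subject_id=subject_id,
        hand=hand,
        medication_state=medication_state,
        **coords,
    )
    if track.missing_mask.all():
        raise EmptyTrackError(f"every frame in {path} misses a required landmark")
    n_missing = int(track.missing_mask.sum())
    if n_missing:
        logger.info("%s: %d/%d frames missing a landmark", path, n_missing, n)
    return track


def write_keypoint_table(track: HandTrack, path, sep: str = ",") -> None:
    """Write a track back out in the long-format dialect read by
    :func:`read_keypoint_table`.  Missing landmarks are omitted (no NaN rows),
    so a read/write round trip reproduces the track bit-exactly."""
    records = []
    has_conf = track.confidence is not None
    for i, frame in enumerate(track.frame_index):
        for name, idx in LANDMARKS.items():
            xy = getattr(track, name)[i]
            if np.isnan(xy).any():
                continue
            rec = {"frame": int(frame), "landmark": idx, "x": xy[0], "y": xy[1]}
            if has_conf and not math.isnan(track.confidence[i]):
                rec["confidence"] = track.confidence[i]
            records.append(rec)
    # %.17g round-trips float64 exactly
    pd.DataFrame.from_records(records).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def default_max_gap(fps: float) -> int:
    """Default gap-fill horizon in frames: 0.2 s at the track's frame rate."""
    return int(round(DEFAULT_MAX_GAP_S * fps))


def fill_gaps(track: HandTrack, max_gap: int | None = None) -> HandTrack:
    """Linearly interpolate short runs of missing frames.

    Runs of at most ``max_gap`` consecutive missing frames (default: 0.2 s
    worth) are filled per landmark and coordinate, interpolating against the
    frame index so non-contiguous tracks are handled correctly.  Longer runs
    stay missing.  Leading and trailing missing frames cannot be interpolated
    and are trimmed.  Non-missing frames are never altered, which makes the
    operation idempotent.
    """
    if max_gap is None:
        max_gap = default_max_gap(track.fps)
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    missing = track.missing_mask
    n = len(track)
    n_missing_before = int(missing.sum())

    # identify runs of missing frames
    runs: list[tuple[int, int]] = []  # [start, stop) indices
    i = 0
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    longest = max((b - a for a, b in runs), default=0)

    coords = {name: getattr(track, name).copy() for name in LANDMARKS}
    n_filled = 0
    fi = track.frame_index.astype(float)
    for a, b in runs:
        interior = a > 0 and b < n
        if interior and (b - a) <= max_gap:
            x0, x1 = fi[a - 1], fi[b]
            for name in LANDMARKS:
                arr = coords[name]
                for c in (0, 1):
                    y0, y1 = arr[a - 1, c], arr[b, c]
                    arr[a:b, c] = y0 + (fi[a:b] - x0) * (y1 - y0) / (x1 - x0)
            n_filled += b - a

    # trim leading/trailing missing
    still_missing = np.isnan(
        np.column_stack([coords[name] for name in LANDMARKS])
    ).any(axis=1)
    keep_from, keep_to = 0, n
    while keep_from < n and still_missing[keep_from]:
        keep_from += 1
    while keep_to > keep_from and still_missing[keep_to - 1]:
        keep_to -= 1
    sl = slice(keep_from, keep_to)
    n_trimmed = n - (keep_to - keep_from)

    report = GapReport(
        n_missing_before=n_missing_before,
        n_filled=n_filled,
        n_trimmed=n_trimmed,
        longest_run=longest,
    )
    return replace(
        track,
        frame_index=track.frame_index[sl],
        confidence=None if track.confidence is None else track.confidence[sl],
        gap_report=report,
        **{name: coords[name][sl] for name in LANDMARKS},
    )
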