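"""Distance, speed and angle signals from a hand-keypoint track.

The core signal is the palm-scaled thumb–index distance

    s(i) = ||thumb_tip(i) - index_tip(i)|| / ||wrist(i) - index_mcp(i)||

computed frame-wise, which makes it invariant to camera distance, in-plane
rotation and (because the palm reference is re-measured every frame) to
transient changes of hand orientation.  The speed signal is the absolute
frame-to-frame displacement of s divided by the actual time gap between the
frames.  An alternative angle signal (the angle at the wrist between the
thumb-tip and index-tip rays) is provided for representation comparisons;
it is view-dependent and serves as the baseline the distance signal is
measured against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySignalError, SignalQualityError
from .keypoint_io import HandTrack

logger = logging.getLogger(__name__)

#: palm lengths below this (in input units) are treated as degenerate
DEGENERATE_PALM_TOL = 1e-6

#: fraction of degenerate/invalid frames above which the recording is rejected
MAX_EXCLUDED_FRAC = 0.20


@dataclass
class DistanceSignal:
    """Palm-scaled thumb–index distance series (dimensionless, >= 0).

    ``times_s`` carries the original frame timestamps so that frames excluded
    upstream (missing keypoints, degenerate palm length) leave real time gaps
    rather than silently compressing the time base.
    """

    values: np.ndarray
    fps: float
    times_s: np.ndarray | None = None
    source_id: str = ""
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s is None:
            self.times_s = np.arange(len(self.values)) / self.fps
        else:
            self.times_s = np.asarray(self.times_s, dtype=float)
        if len(self.values) < 2:
            raise EmptySignalError("distance signal needs >= 2 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("distance signal contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("distance signal contains negative values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


@dataclass
class SpeedSignal:
    """Frame-wise speed of the distance signal (dimensionless units per
    second).  ``times_s`` holds the timestamp of the later frame of each
    consecutive pair, so sample i covers the interval ending at times_s[i]."""

    values: np.ndarray
    fps: float
    times_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s is None:
            self.times_s = (np.arange(len(self.values)) + 1) / self.fps
        else:
            self.times_s = np.asarray(self.times_s, dtype=float)
        if (self.values < 0).any():
            raise ValueError("speed values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AngleSignal:
    """Wrist angle between thumb-tip and index-tip rays, radians in [0, pi]."""

    values: np.ndarray
    fps: float
    times_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_id: str = ""
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s is None:
            self.times_s = np.arange(len(self.values)) / self.fps
        else:
            self.times_s = np.asarray(self.times_s, dtype=float)
        if len(self.values) and (
            (self.values < 0).any() or (self.values > np.pi + 1e-12).any()
        ):
            raise ValueError("angles must lie in [0, pi]")


def _usable(track: HandTrack) -> np.ndarray:
    return ~track.missing_mask


def compute_distance_signal(
    track: HandTrack,
    smooth_window: int | None = None,
) -> DistanceSignal:
    """Build the palm-scaled distance signal from a track.

    Frames with a degenerate palm length (wrist–MCP distance below
    ``DEGENERATE_PALM_TOL``) are excluded and counted; if more than 20 % of
    the usable frames are degenerate the recording is rejected as
    low-quality.  ``smooth_window`` optionally applies a centred moving
    average of odd length (off by default).
    """
    usable = _usable(track)
    if usable.sum() < 2:
        raise EmptySignalError(
            f"track {track.recording_id!r} has {int(usable.sum())} usable frames"
        )
    thumb = track.thumb_tip[usable]
    index = track.index_tip[usable]
    wrist = track.wrist[usable]
    mcp = track.index_mcp[usable]
    times = track.times_s[usable]

    d1 = np.linalg.norm(thumb - index, axis=1)
    d2 = np.linalg.norm(wrist - mcp, axis=1)
    ok = d2 >= DEGENERATE_PALM_TOL
    n_excluded = int((~ok).sum())
    if n_excluded > MAX_EXCLUDED_FRAC * len(d2):
        raise SignalQualityError(
            f"{n_excluded}/{len(d2)} frames have a degenerate palm length"
        )
    if n_excluded:
        logger.info(
            "%s: excluded %d degenerate frames", track.recording_id, n_excluded
        )
    values = d1[ok] / d2[ok]
    if len(values) < 2:
        raise EmptySignalError("fewer than 2 valid frames after exclusions")
    if smooth_window:
        values = moving_average(values, smooth_window)
    return DistanceSignal(
        values=values,
        fps=track.fps,
        times_s=times[ok],
        source_id=track.recording_id,
        n_excluded=n_excluded,
    )


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with an odd window, edges padded by reflection."""
    if window % 2 != 1 or window < 1:
        raise ValueError("smoothing window must be odd and positive")
    if window == 1:
        return np.asarray(values, dtype=float)
    half = window // 2
    padded = np.pad(np.asarray(values, dtype=float), half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def compute_speed_signal(signal: DistanceSignal) -> SpeedSignal:
    """Absolute frame-to-frame displacement over the actual time gap.

    For a gap-free recording the time gap is 1/fps everywhere; excluded
    frames widen individual gaps, which the division handles correctly.
    """
    dt = np.diff(signal.times_s)
    if (dt <= 0).any():
        raise ValueError("timestamps must be strictly increasing")
    values = np.abs(np.diff(signal.values)) / dt
    return SpeedSignal(values=values, fps=signal.fps, times_s=signal.times_s[1:])


def compute_angle_signal(track: HandTrack) -> AngleSignal:
    """Angle at the wrist between the thumb-tip and index-tip rays.

    Frames where either ray has (near-)zero length are excluded and counted.
    The inner product is clamped to [-1, 1] before the arc-cosine.
    """
    usable = _usable(track)
    if usable.sum() < 2:
        raise EmptySignalError(
            f"track {track.recording_id!r} has {int(usable.sum())} usable frames"
        )
    v1 = track.thumb_tip[usable] - track.wrist[usable]
    v2 = track.index_tip[usable] - track.wrist[usable]
    times = track.times_s[usable]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 >= DEGENERATE_PALM_TOL) & (n2 >= DEGENERATE_PALM_TOL)
    n_excluded = int((~ok).sum())
    cosang = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    values = np.arccos(np.clip(cosang, -1.0, 1.0))
    if len(values) < 2:
        raise EmptySignalError("fewer than 2 valid frames after exclusions")
    return AngleSignal(
        values=values,
        fps=track.fps,
        times_s=times[ok],
        source_id=track.recording_id,
        n_excluded=n_excluded,
    )


def write_signal(signal: DistanceSignal | AngleSignal, path, sep: str = ",") -> None:
    """Export a signal as two-column delimited text (time_s, value) with a
    ``.meta`` key-value sidecar carrying fps and source id."""
    import pandas as pd

    pd.DataFrame({"time_s": signal.times_s, "value": signal.values}).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )
    meta_path = str(path) + ".meta"
    with open(meta_path, "w", encoding="utf-8") as fh:
        fh.write(f"fps: {signal.fps}\n")
        fh.write(f"source_id: {signal.source_id}\n")


def read_signal(path, fps: float | None = None, sep: str = ",") -> DistanceSignal:
    """Read a (time_s, value) table back into a :class:`DistanceSignal`.

    fps is taken from the ``.meta`` sidecar when present, otherwise it must
    be supplied.
    """
    import os

    from .keypoint_io import _read_delimited

    df = _read_delimited(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise EmptySignalError(f"{path} is not a (time_s, value) signal file")
    source_id = ""
    meta_path = str(path) + ".meta"
    if os.path.exists(meta_path):
        with open(meta_path, encoding="utf-8") as fh:
            for line in fh:
                key, _, val = line.partition(":")
                key, val = key.strip(), val.strip()
                if key == "fps":
                    fps = float(val)
                elif key == "source_id":
                    source_id = val
    if fps is None:
        raise ValueError(f"fps not given and no sidecar found for {path}")
    return DistanceSignal(
        values=df["value"].to_numpy(float),
        fps=fps,
        times_s=df["time_s"].to_numpy(float),
        source_id=source_id or str(path),
    )
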