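import numpy as np
import pytest

from fingertap import DistanceSignal, HandTrack


def make_sinusoid(
    fps: float = 50.0,
    duration_s: float = 10.0,
    freq_hz: float = 2.0,
    base: float = 1.0,
    amp: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DistanceSignal:
    """base + amp * sin(2 pi f t): peak-to-trough amplitude 2*amp,
    period 1/f."""
    t = np.arange(int(round(duration_s * fps))) / fps
    values = base + amp * np.sin(2 * np.pi * freq_hz * t)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    return DistanceSignal(values=values, fps=fps, source_id="sine")


def make_track(
    thumb: np.ndarray,
    index: np.ndarray,
    wrist: np.ndarray | None = None,
    mcp: np.ndarray | None = None,
    fps: float = 50.0,
) -> HandTrack:
    """Track with a fixed palm (wrist at origin, MCP one unit up) unless
    wrist/mcp trajectories are given."""
    thumb = np.atleast_2d(np.asarray(thumb, dtype=float))
    n = len(thumb)
    if wrist is None:
        wrist = np.tile([0.0, 0.0], (n, 1))
    if mcp is None:
        mcp = np.tile([0.0, 1.0], (n, 1))
    return HandTrack(
        frame_index=np.arange(n),
        wrist=np.asarray(wrist, dtype=float),
        thumb_tip=thumb,
        index_mcp=np.asarray(mcp, dtype=float),
        index_tip=np.atleast_2d(np.asarray(index, dtype=float)),
        fps=fps,
        recording_id="test",
    )


@pytest.fixture
def sinusoid_signal() -> DistanceSignal:
    return make_sinusoid()
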