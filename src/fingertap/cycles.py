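"""Tapping-cycle segmentation: peak/trough detection and per-cycle summaries.

Peaks of the distance signal are frames of full hand opening; troughs are
frames where thumb and index touch.  A cycle runs peak-to-peak.  Per cycle we
summarise:

* amplitude  — signal value at a peak minus the value at its nearest
  preceding trough (the opening excursion),
* duration   — time between successive peaks,
* CAS        — cycle average speed: mean of the speed samples inside the
  cycle window (left-exclusive, right-inclusive),
* CMS        — cycle maximum speed: 95th percentile (linear interpolation)
  of the speed samples in the closed cycle window, robust to single-frame
  keypoint glitches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InsufficientCyclesError
from .signals import DistanceSignal, SpeedSignal


@dataclass(frozen=True)
class PeakParams:
    """Peak-detector settings.

    min_separation_s: minimum time between consecutive peaks.  Voluntary
        tapping rarely exceeds 10 Hz, so 0.1 s rejects double-detections
        without clipping fast tappers.
    min_prominence_frac: required prominence as a fraction of the signal's
        robust range (5th–95th percentile), rejecting jitter peaks while
        staying amplitude-scale-free.
    """

    min_separation_s: float = 0.1
    min_prominence_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.min_separation_s <= 0:
            raise ValueError("min_separation_s must be > 0")
        if not 0 <= self.min_prominence_frac <= 1:
            raise ValueError("min_prominence_frac must be in [0, 1]")


@dataclass
class CycleSet:
    """Per-cycle quantities for one recording.

    With M peaks there are M-1 cycles, hence M-1 durations/CAS/CMS values.
    Amplitudes number at most M (a recording starting at a maximum loses the
    first peak's amplitude).
    """

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    peak_times_s: np.ndarray
    amplitudes: np.ndarray
    durations_s: np.ndarray
    cycle_avg_speeds: np.ndarray
    cycle_max_speeds: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        for name in (
            "peak_indices",
            "trough_indices",
            "peak_times_s",
            "amplitudes",
            "durations_s",
            "cycle_avg_speeds",
            "cycle_max_speeds",
        ):
            setattr(self, name, np.asarray(getattr(self, name)))
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if np.any(self.durations_s <= 0):
            raise ValueError("cycle durations must be positive")
        m = len(self.peak_indices)
        if len(self.durations_s) != m - 1:
            raise ValueError("expected M-1 durations")

    @property
    def n_cycles(self) -> int:
        return len(self.peak_indices) - 1

    def to_frame(self) -> pd.DataFrame:
        """Per-cycle table: one row per peak-to-peak cycle j (ending peak j)."""
        m1 = self.n_cycles
        # amplitudes are peak-aligned; align to the cycle's ending peak
        amp = self.amplitudes[-m1:] if len(self.amplitudes) >= m1 else np.full(
            m1, np.nan
        )
        return pd.DataFrame(
            {
                "cycle_index": np.arange(m1),
                "peak_time_s": self.peak_times_s[1:],
                "amplitude": amp,
                "duration_s": self.durations_s,
                "cas": self.cycle_avg_speeds,
                "cms": self.cycle_max_speeds,
            }
        )


def detect_extrema(
    signal: DistanceSignal, params: PeakParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detect peaks and troughs of the distance signal.

    Troughs are found by running the same detector on the negated signal.
    Between any two consecutive peaks at least one trough is guaranteed: if
    the detector missed one, the minimum of the inter-peak segment is
    inserted, so every cycle has a closing-of-the-fingers event.
    """
    if params is None:
        params = PeakParams()
    values = signal.values
    if len(values) < 3:
        raise InsufficientCyclesError("signal too short for extrema detection", 0)

    distance = max(1, int(round(params.min_separation_s * signal.fps)))
    lo, hi = np.percentile(values, [5, 95])
    prominence = params.min_prominence_frac * (hi - lo)
    kwargs = {"distance": distance}
    if prominence > 0:
        kwargs["prominence"] = prominence

    peaks, _ = find_peaks(values, **kwargs)
    troughs, _ = find_peaks(-values, **kwargs)

    if len(peaks) < 2:
        raise InsufficientCyclesError(
            f"only {len(peaks)} peak(s) detected; need >= 2", len(peaks)
        )

    # guarantee a trough between consecutive peaks, and a closing trough
    # before the first peak when the recording starts with the fingers
    # closed (an endpoint minimum is invisible to the detector)
    trough_set = set(troughs.tolist())
    for a, b in zip(peaks[:-1], peaks[1:]):
        if not any(a < t < b for t in trough_set):
            seg = values[a + 1 : b]
            if len(seg):
                trough_set.add(a + 1 + int(np.argmin(seg)))
    first = peaks[0]
    if first > 0 and not any(t < first for t in trough_set):
        pre = values[:first]
        # only a start with the fingers essentially closed (within 10 % of
        # the excursion above the global minimum) counts as a real trough;
        # a recording starting mid-opening gets no first amplitude
        excursion = values[first] - values.min()
        if pre.min() <= values.min() + 0.1 * excursion:
            trough_set.add(int(np.argmin(pre)))
    troughs = np.array(sorted(trough_set), dtype=int)
    return np.asarray(peaks, dtype=int), troughs


def segment_cycles(
    signal: DistanceSignal,
    speed: SpeedSignal,
    peaks: np.ndarray,
    troughs: np.ndarray,
) -> CycleSet:
    """Assemble per-cycle amplitudes, durations and speed summaries.

    Each peak is paired with the nearest *preceding* trough (fingers close,
    then fully open), so the amplitude measures the opening excursion.  A
    recording that starts at a maximum contributes no amplitude for that
    first peak.  Cycle windows run peak-to-peak.
    """
    peaks = np.asarray(peaks, dtype=int)
    troughs = np.asarray(troughs, dtype=int)
    if len(peaks) < 2:
        raise InsufficientCyclesError(
            f"only {len(peaks)} peak(s); need >= 2", len(peaks)
        )
    values = signal.values
    times = signal.times_s

    amplitudes = []
    for p in peaks:
        prev = troughs[troughs < p]
        if len(prev) == 0:
            continue
        amplitudes.append(values[p] - values[prev[-1]])
    if not amplitudes:
        raise InsufficientCyclesError("no peak has a preceding trough", 0)

    peak_times = times[peaks]
    durations = np.diff(peak_times)

    cas = np.empty(len(peaks) - 1)
    cms = np.empty(len(peaks) - 1)
    st = speed.times_s
    sv = speed.values
    for j in range(1, len(peaks)):
        t0, t1 = peak_times[j - 1], peak_times[j]
        in_open = (st > t0) & (st <= t1)  # (T_{p_{j-1}}, T_{p_j}]
        in_closed = (st >= t0) & (st <= t1)  # [T_{p_{j-1}}, T_{p_j}]
        cas[j - 1] = sv[in_open].mean() if in_open.any() else 0.0
        cms[j - 1] = (
            np.percentile(sv[in_closed], 95) if in_closed.any() else 0.0
        )

    return CycleSet(
        peak_indices=peaks,
        trough_indices=troughs,
        peak_times_s=peak_times,
        amplitudes=np.asarray(amplitudes, dtype=float),
        durations_s=durations,
        cycle_avg_speeds=cas,
        cycle_max_speeds=cms,
        source_id=signal.source_id,
    )


def write_cycles(cycles: CycleSet, path, sep: str = ",") -> None:
    """Export the per-cycle table as delimited text."""
    cycles.to_frame().to_csv(path, sep=sep, index=False)
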