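"""The interpretable motor-deficit features of one tapping recording.

Twelve kinematic features summarise four clinical domains plus two combined
speed measures:

* hypokinesia          — amp_avg: mean opening amplitude
* bradykinesia         — cd_avg: mean peak-to-peak cycle duration (s)
* combined speed       — cas_avg, cms_avg: mean cycle average / maximum speed
* sequence effect      — amp_slope, cd_slope, speed_slope: OLS linear trends
                          of amplitude, duration and CAS against cycle index
* hesitation-halts     — amp_cv, cd_cv, cms_cv, cas_cv: coefficients of
                          variation; n_interruptions: cycles longer than
                          twice the median cycle duration

Conventions follow the defining formulas: the amplitude CV normalises the
squared-deviation sum by the peak count M (its printed form), the other CVs
by the number of cycles M-1; a ``consistent_cv`` switch unifies all four to
the count of contributing terms.  Averages always divide by the number of
terms actually available.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycles import CycleSet, PeakParams, detect_extrema, segment_cycles
from .errors import FingertapError, InsufficientCyclesError
from .signals import DistanceSignal, compute_speed_signal

#: canonical model-feature column order
FEATURE_NAMES = [
    "amp_avg",
    "cd_avg",
    "cas_avg",
    "cms_avg",
    "amp_slope",
    "cd_slope",
    "speed_slope",
    "amp_cv",
    "cd_cv",
    "cms_cv",
    "cas_cv",
    "n_interruptions",
]

#: interruption rule: a cycle counts as an interruption when its duration
#: exceeds this multiple of the median cycle duration
INTERRUPTION_MEDIAN_FACTOR = 2.0

MIN_CYCLES_FOR_SLOPE = 3


@dataclass
class FeatureVector:
    """One recording's feature row; ``valid=False`` carries the failure reason."""

    amp_avg: float = np.nan
    cd_avg: float = np.nan
    cas_avg: float = np.nan
    cms_avg: float = np.nan
    amp_slope: float = np.nan
    cd_slope: float = np.nan
    speed_slope: float = np.nan
    amp_cv: float = np.nan
    cd_cv: float = np.nan
    cms_cv: float = np.nan
    cas_cv: float = np.nan
    n_interruptions: float = np.nan
    n_cycles: int = 0
    valid: bool = True
    reason: str = ""
    recording_id: str = ""
    subject_id: str = ""

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def values(self) -> np.ndarray:
        """The 12 kinematic features in canonical order."""
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def hypokinesia_features(cycles: CycleSet) -> float:
    """Mean opening amplitude over all computed amplitudes."""
    if len(cycles.amplitudes) == 0:
        raise InsufficientCyclesError("no amplitudes available", 0)
    return float(np.mean(cycles.amplitudes))


def bradykinesia_features(cycles: CycleSet) -> float:
    """Mean peak-to-peak cycle duration in seconds."""
    if len(cycles.durations_s) == 0:
        raise InsufficientCyclesError("fewer than 2 peaks", len(cycles.peak_indices))
    return float(np.mean(cycles.durations_s))


def combined_speed_features(cycles: CycleSet) -> tuple[float, float]:
    """Mean cycle average speed and mean cycle maximum (95th pct) speed."""
    if cycles.n_cycles < 1:
        raise InsufficientCyclesError("fewer than 2 peaks", len(cycles.peak_indices))
    return float(np.mean(cycles.cycle_avg_speeds)), float(
        np.mean(cycles.cycle_max_speeds)
    )


def _ols_slope(y: np.ndarray, x: np.ndarray | None = None) -> float:
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(len(y), dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def sequence_effect_features(
    cycles: CycleSet, regressor: str = "index"
) -> tuple[float, float, float]:
    """OLS slopes of amplitude, cycle duration and CAS across the task.

    ``regressor='index'`` regresses against cycle number 0,1,2,… (slopes in
    per-cycle units); ``'time'`` regresses against the elapsed time of each
    cycle's closing peak (slopes per second).  A slope needs at least
    three points — two points always fit exactly and carry no trend
    information.
    """
    if regressor not in ("index", "time"):
        raise ValueError("regressor must be 'index' or 'time'")

    def x_for(n: int, times: np.ndarray) -> np.ndarray | None:
        return None if regressor == "index" else times[:n]

    amps = cycles.amplitudes
    durs = cycles.durations_s
    cas = cycles.cycle_avg_speeds
    if min(len(amps), len(durs), len(cas)) < MIN_CYCLES_FOR_SLOPE:
        raise InsufficientCyclesError(
            f"need >= {MIN_CYCLES_FOR_SLOPE} cycles for trend fitting",
            cycles.n_cycles,
        )
    # peak-aligned time axes: amplitudes at their peaks, durations/CAS at the
    # cycle's closing peak
    amp_times = cycles.peak_times_s[-len(amps):]
    cyc_times = cycles.peak_times_s[1:]
    amp_slope = _ols_slope(amps, x_for(len(amps), amp_times))
    cd_slope = _ols_slope(durs, x_for(len(durs), cyc_times))
    speed_slope = _ols_slope(cas, x_for(len(cas), cyc_times))
    return amp_slope, cd_slope, speed_slope


def _cv(x: np.ndarray, denom: int) -> float:
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise FingertapError("zero mean in CV denominator")
    sd = np.sqrt(np.sum((x - mean) ** 2) / denom)
    return float(sd / mean)


def hesitation_halt_features(
    cycles: CycleSet, consistent_cv: bool = False
) -> tuple[float, float, float, float, int]:
    """Coefficients of variation plus the interruption count.

    The amplitude CV divides the squared-deviation sum by the peak count M
    (its defining form); with ``consistent_cv=True`` it divides by the number
    of amplitudes instead, matching the other three CVs which always use the
    number of contributing cycles.  An interruption is a cycle whose duration
    exceeds twice the median cycle duration.
    """
    if cycles.n_cycles < 2:
        raise InsufficientCyclesError(
            "need >= 2 cycles for variability features", cycles.n_cycles
        )
    m_peaks = len(cycles.peak_indices)
    amp_denom = len(cycles.amplitudes) if consistent_cv else m_peaks
    amp_cv = _cv(cycles.amplitudes, amp_denom)
    n_cyc = cycles.n_cycles
    cd_cv = _cv(cycles.durations_s, n_cyc)
    cms_cv = _cv(cycles.cycle_max_speeds, n_cyc)
    cas_cv = _cv(cycles.cycle_avg_speeds, n_cyc)
    n_interruptions = count_interruptions(cycles.durations_s)
    return amp_cv, cd_cv, cms_cv, cas_cv, n_interruptions


def count_interruptions(durations_s: np.ndarray) -> int:
    """Cycles whose duration exceeds twice the median cycle duration."""
    durations_s = np.asarray(durations_s, dtype=float)
    if len(durations_s) == 0:
        return 0
    threshold = INTERRUPTION_MEDIAN_FACTOR * np.median(durations_s)
    return int(np.sum(durations_s > threshold))


def extract_all(
    signal: DistanceSignal,
    params: PeakParams | None = None,
    consistent_cv: bool = False,
    slope_regressor: str = "index",
    recording_id: str = "",
    subject_id: str = "",
) -> FeatureVector:
    """Run the full signal -> cycles -> features pipeline for one recording.

    Any pipeline error is materialised as an invalid :class:`FeatureVector`
    carrying the reason; this function never raises past its boundary for
    data-dependent failures.
    """
    rid = recording_id or signal.source_id
    try:
        speed = compute_speed_signal(signal)
        peaks, troughs = detect_extrema(signal, params)
        cycles = segment_cycles(signal, speed, peaks, troughs)
        amp_avg = hypokinesia_features(cycles)
        cd_avg = bradykinesia_features(cycles)
        cas_avg, cms_avg = combined_speed_features(cycles)
        amp_slope, cd_slope, speed_slope = sequence_effect_features(
            cycles, regressor=slope_regressor
        )
        amp_cv, cd_cv, cms_cv, cas_cv, n_int = hesitation_halt_features(
            cycles, consistent_cv=consistent_cv
        )
    except FingertapError as exc:
        return FeatureVector(
            valid=False,
            reason=str(exc),
            recording_id=rid,
            subject_id=subject_id,
        )
    return FeatureVector(
        amp_avg=amp_avg,
        cd_avg=cd_avg,
        cas_avg=cas_avg,
        cms_avg=cms_avg,
        amp_slope=amp_slope,
        cd_slope=cd_slope,
        speed_slope=speed_slope,
        amp_cv=amp_cv,
        cd_cv=cd_cv,
        cms_cv=cms_cv,
        cas_cv=cas_cv,
        n_interruptions=float(n_int),
        n_cycles=cycles.n_cycles,
        valid=True,
        recording_id=rid,
        subject_id=subject_id,
    )


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a table, one row per recording.

    Invalid recordings keep their row with empty feature cells and a filled
    ``reason`` column, so bookkeeping survives the export.
    """
    rows = [fv.as_dict() for fv in features]
    df = pd.DataFrame(rows)
    cols = ["recording_id", "subject_id"] + FEATURE_NAMES + [
        "n_cycles",
        "valid",
        "reason",
    ]
    return df[cols]
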