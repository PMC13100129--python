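"""Synthetic quasi-periodic tapping signals with known ground truth.

The simulator realises exactly the statistical structure the features
measure: per-cycle amplitudes and durations with linear trends, multiplicative
log-normal cycle-to-cycle variability (which keeps both positive), discrete
pauses inserted at cycle boundaries, and additive observation noise.  It does
not attempt to model keypoint geometry, tremor or camera effects — it is a
ground-truth generator for parameter-recovery testing, not a biomechanical
model.

A cycle starts and ends with the fingers closed (trough level), opening to
trough + amplitude mid-cycle.  Waveforms: ``sinusoid`` and ``raised_cosine``
are the same shape, sin^2(pi * phase) — a sinusoid started at the trough *is*
the raised cosine — and ``triangle`` gives piecewise-constant speed.
Interruptions are flat segments at trough level of length
``interruption_factor`` x the median programmed cycle duration, inserted at
uniformly chosen internal cycle boundaries; a factor > 2 guarantees the
resulting peak-to-peak gap exceeds the twice-the-median detection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FEATURE_NAMES, extract_all
from .severity import LABELS, SeverityDataset, SeverityLabel
from .signals import DistanceSignal

#: resting thumb–index distance (palm-scaled units) when the fingers touch
DEFAULT_TROUGH_LEVEL = 0.2

WAVEFORMS = ("sinusoid", "raised_cosine", "triangle")


@dataclass(frozen=True)
class TapSimParams:
    """Programmed ground truth of one simulated recording.

    Defaults describe an unimpaired 10-second tapping bout at 50 fps: unit
    opening amplitude, 0.35 s cycles (~2.9 Hz), no trends, no pauses.
    Slopes are fractional per cycle: cycle j has trend factor
    (1 + slope * j).  amp_cv / cd_cv are the standard deviations of the
    log-normal cycle multipliers, i.e. approximately the programmed
    coefficients of variation.
    """

    fps: float = 50.0
    duration_s: float = 10.0
    base_amplitude: float = 1.0
    base_cycle_s: float = 0.35
    amp_slope_per_cycle: float = 0.0
    cd_slope_per_cycle: float = 0.0
    amp_cv: float = 0.0
    cd_cv: float = 0.0
    n_interruptions: int = 0
    interruption_factor: float = 3.0
    waveform: str = "sinusoid"
    noise_sd: float = 0.0
    trough_level: float = DEFAULT_TROUGH_LEVEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValidationError("fps and duration_s must be positive")
        if self.base_amplitude <= 0 or self.base_cycle_s <= 0:
            raise ValidationError("base amplitude and cycle duration must be > 0")
        if self.amp_cv < 0 or self.cd_cv < 0 or self.noise_sd < 0:
            raise ValidationError("variability parameters must be >= 0")
        if self.n_interruptions < 0:
            raise ValidationError("n_interruptions must be >= 0")
        if self.n_interruptions > 0 and self.interruption_factor <= 2:
            raise ValidationError(
                "interruption_factor must exceed 2 (the detection threshold)"
            )
        if self.waveform not in WAVEFORMS:
            raise ValidationError(f"waveform must be one of {WAVEFORMS}")


@dataclass
class TapGroundTruth:
    """Everything that was programmed into one simulated recording."""

    params: TapSimParams
    amplitudes: np.ndarray
    durations_s: np.ndarray
    pause_boundaries: np.ndarray
    pause_length_s: float

    @property
    def amp_avg(self) -> float:
        return float(np.mean(self.amplitudes))

    @property
    def cd_avg(self) -> float:
        return float(np.mean(self.durations_s))

    @property
    def amp_slope(self) -> float:
        """Programmed amplitude trend in signal units per cycle."""
        return self.params.base_amplitude * self.params.amp_slope_per_cycle

    @property
    def cd_slope(self) -> float:
        """Programmed duration trend in seconds per cycle."""
        return self.params.base_cycle_s * self.params.cd_slope_per_cycle

    @property
    def n_cycles(self) -> int:
        return len(self.durations_s)

    @property
    def n_interruptions(self) -> int:
        return len(self.pause_boundaries)

    @property
    def peak_gap_durations_s(self) -> np.ndarray:
        """Programmed peak-to-peak gaps, the quantity cycle durations measure.

        The waveform peaks mid-cycle, so the gap between peaks j and j+1 is
        (D_j + D_{j+1}) / 2, plus the pause length where a pause was inserted
        at that boundary.
        """
        gaps = (self.durations_s[:-1] + self.durations_s[1:]) / 2.0
        for b in self.pause_boundaries:
            gaps[b - 1] += self.pause_length_s
        return gaps

    @property
    def gap_avg_speeds(self) -> np.ndarray:
        """Programmed mean speed per peak-to-peak gap: the closing+opening
        travel (A_j + A_{j+1}) over the gap duration."""
        a = self.amplitudes
        return (a[:-1] + a[1:]) / self.peak_gap_durations_s


def _shape(phase: np.ndarray, waveform: str) -> np.ndarray:
    if waveform in ("sinusoid", "raised_cosine"):
        return np.sin(np.pi * phase) ** 2
    # triangle: constant-speed open/close
    return 1.0 - np.abs(2.0 * phase - 1.0)


def simulate_tapping(
    params: TapSimParams,
) -> tuple[DistanceSignal, TapGroundTruth]:
    """Generate one distance signal plus its ground-truth record.

    Deterministic for a fixed ``params.seed``.  Raises if fewer than three
    cycles fit into ``duration_s`` or if more interruptions are requested
    than internal cycle boundaries exist.
    """
    rng = np.random.default_rng(params.seed)

    # draw per-cycle amplitudes/durations until the tapping time is used up
    amps: list[float] = []
    durs: list[float] = []
    total = 0.0
    j = 0
    while True:
        trend_a = max(1.0 + params.amp_slope_per_cycle * j, 0.05)
        trend_d = max(1.0 + params.cd_slope_per_cycle * j, 0.05)
        a = params.base_amplitude * trend_a * np.exp(rng.normal(0.0, params.amp_cv))
        d = params.base_cycle_s * trend_d * np.exp(rng.normal(0.0, params.cd_cv))
        if total + d > params.duration_s:
            break
        amps.append(a)
        durs.append(d)
        total += d
        j += 1
    if len(durs) < 3:
        raise ValidationError(
            f"only {len(durs)} cycles fit in {params.duration_s} s; need >= 3"
        )
    amplitudes = np.asarray(amps)
    durations = np.asarray(durs)
    n_cycles = len(durations)

    # choose internal boundaries (after cycle b, b = 1..n_cycles-1) for pauses
    n_boundaries = n_cycles - 1
    if params.n_interruptions > n_boundaries:
        raise ValidationError(
            f"{params.n_interruptions} interruptions do not fit between "
            f"{n_cycles} cycles"
        )
    boundaries = np.sort(
        rng.choice(np.arange(1, n_cycles), size=params.n_interruptions, replace=False)
    )
    pause_len = params.interruption_factor * float(np.median(durations))

    # assemble piecewise segments: (duration, amplitude or None for a pause)
    segments: list[tuple[float, float | None]] = []
    for c in range(n_cycles):
        segments.append((durations[c], amplitudes[c]))
        if c + 1 in boundaries:
            segments.append((pause_len, None))

    total_time = sum(d for d, _ in segments)
    n_samples = int(np.floor(total_time * params.fps)) + 1
    t = np.arange(n_samples) / params.fps

    values = np.full(n_samples, params.trough_level)
    start = 0.0
    for dur, amp in segments:
        if amp is not None:
            in_seg = (t >= start) & (t < start + dur)
            phase = (t[in_seg] - start) / dur
            values[in_seg] = params.trough_level + amp * _shape(
                phase, params.waveform
            )
        start += dur

    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, n_samples)
    values = np.clip(values, 0.0, None)

    signal = DistanceSignal(
        values=values,
        fps=params.fps,
        source_id=f"sim-seed{params.seed}",
    )
    truth = TapGroundTruth(
        params=params,
        amplitudes=amplitudes,
        durations_s=durations,
        pause_boundaries=boundaries,
        pause_length_s=pause_len,
    )
    return signal, truth


# --------------------------------------------------------------------------
# cohort generation

#: per-class parameter ranges (uniform draws at the subject level).  Values
#: follow the clinical picture the severity groups encode — Mild taps are
#: large, fast and regular (around 0.35 s cycles); Severe taps are small,
#: slow (cycle durations around and beyond 0.42 s), irregular and interrupted.
#: Ranges deliberately overlap between neighbouring groups, as real severity
#: groups do.
DEFAULT_CLASS_PROFILES: dict[SeverityLabel, dict] = {
    SeverityLabel.MILD: {
        "base_amplitude": (0.9, 1.3),
        "base_cycle_s": (0.28, 0.42),
        "amp_cv": (0.03, 0.08),
        "cd_cv": (0.03, 0.08),
        "amp_slope_per_cycle": (-0.004, 0.0),
        "cd_slope_per_cycle": (0.0, 0.002),
        "n_interruptions": (0, 1),
    },
    SeverityLabel.MODERATE: {
        "base_amplitude": (0.6, 1.0),
        "base_cycle_s": (0.34, 0.50),
        "amp_cv": (0.06, 0.14),
        "cd_cv": (0.06, 0.14),
        "amp_slope_per_cycle": (-0.008, -0.001),
        "cd_slope_per_cycle": (0.0, 0.004),
        "n_interruptions": (0, 3),
    },
    SeverityLabel.SEVERE: {
        "base_amplitude": (0.3, 0.7),
        "base_cycle_s": (0.40, 0.60),
        "amp_cv": (0.10, 0.22),
        "cd_cv": (0.10, 0.20),
        "amp_slope_per_cycle": (-0.012, -0.002),
        "cd_slope_per_cycle": (0.001, 0.006),
        "n_interruptions": (1, 5),
    },
}

#: per-recording observation noise used by the cohort generator
COHORT_NOISE_SD = 0.02


def _draw_subject_params(
    profile: dict, rng: np.random.Generator, fps: float, duration_s: float
) -> dict:
    drawn = {}
    for key, rng_or_val in profile.items():
        if isinstance(rng_or_val, (tuple, list)):
            lo, hi = rng_or_val
            if key == "n_interruptions":
                drawn[key] = int(rng.integers(lo, hi + 1))
            else:
                drawn[key] = float(rng.uniform(lo, hi))
        else:
            drawn[key] = rng_or_val
    drawn.setdefault("fps", fps)
    drawn.setdefault("duration_s", duration_s)
    drawn.setdefault("noise_sd", COHORT_NOISE_SD)
    return drawn


def _jitter_recording(base: dict, rng: np.random.Generator) -> dict:
    """Small within-subject recording-to-recording variation."""
    out = dict(base)
    for key in ("base_amplitude", "base_cycle_s"):
        if key in base:
            out[key] = base[key] * rng.uniform(0.95, 1.05)
    for key in ("amp_cv", "cd_cv"):
        if key in base:
            out[key] = max(base[key] * rng.uniform(0.9, 1.1), 0.0)
    if base.get("n_interruptions", 0) > 0:
        out["n_interruptions"] = max(
            0, int(base["n_interruptions"] + rng.integers(-1, 2))
        )
    return out


def simulate_cohort(
    n_subjects: int = 60,
    recordings_per_subject: int = 2,
    class_profiles: dict | None = None,
    seed: int = 0,
    fps: float = 50.0,
    duration_s: float = 10.0,
) -> tuple[SeverityDataset, pd.DataFrame]:
    """Simulate a labelled cohort and extract its feature matrix.

    Subjects are assigned to severity groups round-robin (balanced classes).
    Each subject draws its parameters once from the class profile (the
    subject-level random effect); each recording jitters them slightly.
    Features come from the real extraction pipeline, so the returned dataset
    exercises the full signal -> features path.  Reproducible given ``seed``.
    """
    if class_profiles is None:
        class_profiles = DEFAULT_CLASS_PROFILES
    labels = [lbl for lbl in LABELS if lbl in class_profiles]
    if len(labels) < 2:
        raise ValidationError("need >= 2 classes with non-empty profiles")
    for lbl in labels:
        if not class_profiles[lbl]:
            raise ValidationError(f"empty class profile for {lbl}")

    rng = np.random.default_rng(seed)
    rows_X, ys, subs, recs, truth_rows = [], [], [], [], []
    for s in range(n_subjects):
        label = labels[s % len(labels)]
        subject_id = f"S{s:03d}"
        base = _draw_subject_params(class_profiles[label], rng, fps, duration_s)
        for r in range(recordings_per_subject):
            p = _jitter_recording(base, rng)
            p["seed"] = int(rng.integers(0, 2**31 - 1))
            params = TapSimParams(**p)
            recording_id = f"{subject_id}-R{r}"
            signal, truth = simulate_tapping(params)
            signal = replace(signal, source_id=recording_id)
            fv = extract_all(
                signal, recording_id=recording_id, subject_id=subject_id
            )
            if not fv.valid:
                continue
            rows_X.append(fv.values())
            ys.append(int(label))
            subs.append(subject_id)
            recs.append(recording_id)
            truth_rows.append(
                {
                    "recording_id": recording_id,
                    "subject_id": subject_id,
                    "label": str(label),
                    "true_amp_avg": truth.amp_avg,
                    "true_cd_avg": truth.cd_avg,
                    "true_amp_slope": truth.amp_slope,
                    "true_cd_slope": truth.cd_slope,
                    "true_amp_cv": params.amp_cv,
                    "true_cd_cv": params.cd_cv,
                    "true_n_interruptions": truth.n_interruptions,
                    "n_cycles": truth.n_cycles,
                }
            )

    dataset = SeverityDataset(
        X=np.asarray(rows_X),
        y=np.asarray(ys),
        subject_ids=np.asarray(subs),
        recording_ids=np.asarray(recs),
        feature_names=list(FEATURE_NAMES),
    )
    return dataset, pd.DataFrame(truth_rows)
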