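"""Threshold-based burst detection on intensity traces.

An event is a maximal run of frames above the intensity threshold; brief
sub-threshold dropouts are bridged, too-short runs discarded, and runs touching
the trace boundaries flagged as censored.  The dwell time is the run length
times the frame interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import DEFAULT_THRESHOLD, IntensityTrace
from .types import DwellTimeSet, Event


@dataclass(frozen=True)
class DetectionConfig:
    threshold: float = DEFAULT_THRESHOLD
    min_dwell_frames: int = 2
    gap_tolerance_frames: int = 1
    exclude_censored: bool = True

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise ValueError("threshold must be > 0")
        if self.min_dwell_frames < 1:
            raise ValueError("min_dwell_frames must be >= 1")
        if self.gap_tolerance_frames < 0:
            raise ValueError("gap_tolerance_frames must be >= 0")


@dataclass
class RecoveryReport:
    """Match statistics between detected events and ground truth."""

    n_truth: int
    n_detected: int
    n_matched: int
    n_missed: int
    n_spurious: int
    dwell_errors: np.ndarray  # detected minus true dwell, per match, seconds

    @property
    def match_fraction(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def max_abs_dwell_error(self) -> float:
        return float(np.max(np.abs(self.dwell_errors))) if len(self.dwell_errors) else 0.0


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_events(
    trace: IntensityTrace, config: DetectionConfig | None = None, condition: str = ""
) -> DwellTimeSet:
    """Extract dwell times from one trace.

    Runs separated by at most ``gap_tolerance_frames`` sub-threshold frames are
    merged; merged runs shorter than ``min_dwell_frames`` are discarded; events
    touching either trace boundary are censored and, by default, excluded.
    """
    if config is None:
        config = DetectionConfig()
    steps = np.diff(trace.times)
    if steps.size == 0:
        raise ValueError("trace too short for detection")
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
        raise ValueError("trace grid is not uniform")
    dt = float(steps[0])
    mask = trace.intensities > config.threshold
    runs = _runs_above(mask)

    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] <= config.gap_tolerance_frames:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    n_frames = mask.size
    events = []
    for start, stop in merged:
        if stop - start < config.min_dwell_frames:
            continue
        censored = start == 0 or stop == n_frames
        if censored and config.exclude_censored:
            continue
        events.append(Event(start * dt, stop * dt, censored))

    return DwellTimeSet(
        dwells=np.array([e.dwell for e in events]),
        condition=condition,
        provenance="detected",
        events=events,
    )


def recovery_report(
    detected: DwellTimeSet, truth: list[Event], tolerance: float = 0.0
) -> RecoveryReport:
    """Match detected events to ground-truth intervals by overlap.

    Each truth interval (optionally dilated by ``tolerance`` seconds) is
    matched greedily, by decreasing overlap, to at most one detected event.
    """
    if detected.events is None:
        raise ValueError("detected set carries no event intervals")
    candidates = []
    for ti, t in enumerate(truth):
        t_lo, t_hi = t.start - tolerance, t.end + tolerance
        for di, d in enumerate(detected.events):
            overlap = min(t_hi, d.end) - max(t_lo, d.start)
            if overlap > 0:
                candidates.append((overlap, ti, di))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    matched_t: set[int] = set()
    matched_d: set[int] = set()
    errors = []
    for _overlap, ti, di in candidates:
        if ti in matched_t or di in matched_d:
            continue
        matched_t.add(ti)
        matched_d.add(di)
        errors.append(detected.events[di].dwell - truth[ti].dwell)

    return RecoveryReport(
        n_truth=len(truth),
        n_detected=len(detected.events),
        n_matched=len(matched_t),
        n_missed=len(truth) - len(matched_t),
        n_spurious=len(detected.events) - len(matched_d),
        dwell_errors=np.asarray(errors, dtype=float),
    )
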