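"""Synthetic per-spot fluorescence traces and dwell-time datasets.

Emulates the single-molecule experiment at the trace level: a 100 ms frame
grid, Gaussian baseline noise, and square fluorescence bursts whose durations
come from an exponential distribution or from the two-step kinetic scheme.
Every artifact is reconstructible from its config and seed.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stochastic_sim import DEFAULT_SEED, SchemeSpec, simulate_ensemble
from .types import DwellTimeSet, Event

DEFAULT_THRESHOLD = 5000.0  # A.U.; the default burst-selection threshold


@dataclass(frozen=True)
class TraceConfig:
    """Parameters of one synthetic intensity trace.

    ``dwell_source`` is either an exponential mean in seconds (float) or a
    :class:`~dwellkin.stochastic_sim.SchemeSpec`.
    """

    dwell_source: float | SchemeSpec
    frame_interval: float = 0.1
    duration: float = 600.0
    baseline: float = 500.0
    burst_amplitude: float = 8000.0
    noise_sd: float = 300.0
    arrival_rate: float = 0.01
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        if self.noise_sd < 0 or self.arrival_rate < 0:
            raise ValueError("noise_sd and arrival_rate must be >= 0")
        if isinstance(self.dwell_source, (int, float)) and not (self.dwell_source > 0):
            raise ValueError("exponential dwell mean must be > 0")
        if (
            self.baseline + self.burst_amplitude
            < DEFAULT_THRESHOLD + 3 * self.noise_sd
        ):
            warnings.warn(
                "burst level is within 3 noise SDs of the default detection "
                f"threshold ({DEFAULT_THRESHOLD} A.U.); detection may be unreliable",
                UserWarning,
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.dwell_source, SchemeSpec):
            d["dwell_source"] = {"scheme": asdict(self.dwell_source)}
        return d


@dataclass
class IntensityTrace:
    """Uniform-grid intensity series for one spot, with generation ground truth."""

    times: np.ndarray
    intensities: np.ndarray
    ground_truth: list[Event] = field(default_factory=list)
    config: TraceConfig | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
                raise ValueError("times must form a uniform grid")

    @property
    def frame_interval(self) -> float:
        if self.times.size < 2:
            raise ValueError("trace too short to infer frame interval")
        return float(self.times[1] - self.times[0])

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "intensity_au": self.intensities}).to_csv(
            path, index=False
        )
        sidecar = {
            "ground_truth": [
                {"start": e.start, "end": e.end, "censored": e.censored}
                for e in self.ground_truth
            ],
        }
        if self.config is not None:
            sidecar["config"] = self.config.to_dict()
        path.with_suffix(".meta.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntensityTrace":
        path = Path(path)
        df = pd.read_csv(path)
        ground_truth: list[Event] = []
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            ground_truth = [
                Event(d["start"], d["end"], d.get("censored", False))
                for d in meta.get("ground_truth", [])
            ]
        return cls(
            times=df["time_s"].to_numpy(float),
            intensities=df["intensity_au"].to_numpy(float),
            ground_truth=ground_truth,
        )


def generate_dwells(
    n: int,
    seed: int = DEFAULT_SEED,
    mean: float | None = None,
    scheme: SchemeSpec | None = None,
    condition: str = "",
) -> DwellTimeSet:
    """``n`` ground-truth dwell times, exponential or scheme-sampled."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if (mean is None) == (scheme is None):
        raise ValueError("provide exactly one of mean or scheme")
    if mean is not None:
        if not (mean > 0):
            raise ValueError(f"mean must be > 0, got {mean}")
        rng = np.random.default_rng(seed)
        dwells = rng.exponential(mean, n)
        return DwellTimeSet(dwells, condition=condition, seed=seed)
    result = simulate_ensemble(scheme, n, seed)
    return DwellTimeSet(result.dwells, condition=condition or scheme.label, seed=seed)


def _draw_dwell(config: TraceConfig, rng: np.random.Generator) -> float:
    src = config.dwell_source
    if isinstance(src, SchemeSpec):
        total1 = src.rate_1to2 + src.rate_1to0
        p_rebind = src.rate_1to2 / total1
        t = 0.0
        while True:
            t += rng.exponential(1.0 / src.rate_2to1)
            t += rng.exponential(1.0 / total1)
            if rng.random() >= p_rebind:
                return t
    return rng.exponential(float(src))


def generate_trace(config: TraceConfig) -> IntensityTrace:
    """One synthetic trace: baseline + noise, square bursts at Poisson arrivals.

    Prospective events that would overlap the previous accepted burst are
    rejected (one fluorophore-equivalent per spot), so recorded ground-truth
    intervals never overlap.  Bursts running past the trace end are truncated
    and flagged censored.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration / config.frame_interval))
    times = np.arange(n_frames) * config.frame_interval
    intensities = config.baseline + rng.normal(0.0, config.noise_sd, n_frames)

    events: list[Event] = []
    if config.arrival_rate > 0:
        t = rng.exponential(1.0 / config.arrival_rate)
        last_end = -np.inf
        while t < config.duration:
            dwell = _draw_dwell(config, rng)
            if t >= last_end:  # reject overlapping prospective events
                end = t + dwell
                censored = end > config.duration
                events.append(Event(t, min(end, config.duration), censored))
                last_end = end
            t += rng.exponential(1.0 / config.arrival_rate)

    for event in events:
        i0 = int(np.ceil(event.start / config.frame_interval - 1e-9))
        i1 = int(np.ceil(event.end / config.frame_interval - 1e-9))
        intensities[i0:i1] += config.burst_amplitude

    return IntensityTrace(times, intensities, events, config)
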