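"""Shared data containers used across generation, detection and fitting stages."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Event:
    """One burst interval on a trace, in seconds from trace start."""

    start: float
    end: float
    censored: bool = False

    @property
    def dwell(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "Event") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class DwellTimeSet:
    """Complex lifetimes for one experimental condition.

    ``dwells`` are strictly positive durations in seconds.  ``provenance``
    records whether they were simulated directly or detected on a trace; in
    the latter case ``events`` holds the per-event intervals.
    """

    dwells: np.ndarray
    condition: str = ""
    provenance: str = "simulated"
    events: list[Event] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.dwells = np.asarray(self.dwells, dtype=float)
        if self.dwells.ndim != 1:
            raise ValueError("dwells must be one-dimensional")
        if self.dwells.size and not np.all(self.dwells > 0):
            raise ValueError("all dwells must be strictly positive")

    @property
    def n(self) -> int:
        return int(self.dwells.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.dwells))

    @property
    def sem(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(np.std(self.dwells, ddof=1) / np.sqrt(self.n))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"condition": self.condition, "dwell_s": self.dwells})
        if self.events is not None:
            df["start_s"] = [e.start for e in self.events]
            df["end_s"] = [e.end for e in self.events]
            df["censored"] = [e.censored for e in self.events]
        return df

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if metadata is not None:
            sidecar = path.with_suffix(".meta.json")
            sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, condition: str | None = None) -> "DwellTimeSet":
        df = pd.read_csv(path)
        if condition is not None:
            df = df[df["condition"] == condition]
        elif "condition" in df.columns and df["condition"].nunique() == 1:
            condition = str(df["condition"].iloc[0])
        events = None
        if {"start_s", "end_s"}.issubset(df.columns):
            censored = df["censored"] if "censored" in df.columns else [False] * len(df)
            events = [
                Event(float(s), float(e), bool(c))
                for s, e, c in zip(df["start_s"], df["end_s"], censored)
            ]
        return cls(
            dwells=df["dwell_s"].to_numpy(float),
            condition=condition or "",
            provenance="detected" if events else "simulated",
            events=events,
        )
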