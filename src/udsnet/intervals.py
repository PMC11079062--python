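"""State sequences and epoch sets: alternating Up/Down intervals in seconds.

Time convention throughout the package: seconds, half-open intervals
[start, end), t=0 at recording/simulation start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

UP = "U"
DOWN = "D"

__all__ = ["UP", "DOWN", "StateSequence", "EpochSet"]


@dataclass
class StateSequence:
    """Strictly alternating Up/Down intervals over synchronized data.

    ``intervals`` is a list of (start, end, label) with label 'U' or 'D',
    sorted and non-overlapping.  Within each contiguous run (one
    synchronized epoch) the intervals are gap-free and the labels strictly
    alternate; a gap (an excised desynchronized epoch) may separate runs,
    across which labels are unconstrained.  ``source`` records what was
    segmented ('vm', 'lfp' or 'model').
    """

    intervals: List[Tuple[float, float, str]]
    source: str = "model"

    def __post_init__(self) -> None:
        prev_label = None
        prev_end = None
        for (s, e, lab) in self.intervals:
            if lab not in (UP, DOWN):
                raise ValueError(f"bad state label {lab!r}")
            if e <= s:
                raise ValueError(f"non-positive duration interval ({s}, {e})")
            if prev_end is not None:
                if s < prev_end - 1e-9:
                    raise ValueError("intervals must not overlap")
                contiguous = abs(s - prev_end) <= 1e-9
                if contiguous and lab == prev_label:
                    raise ValueError(
                        "state labels must strictly alternate within an epoch")
            prev_label, prev_end = lab, e

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _, _ in self.intervals])

    @property
    def ends(self) -> np.ndarray:
        return np.array([e for _, e, _ in self.intervals])

    @property
    def labels(self) -> List[str]:
        return [lab for _, _, lab in self.intervals]

    @property
    def t_start(self) -> float:
        return self.intervals[0][0]

    @property
    def t_end(self) -> float:
        return self.intervals[-1][1]

    def durations(self, label: str | None = None) -> np.ndarray:
        return np.array([e - s for s, e, lab in self.intervals
                         if label is None or lab == label])

    def swap_labels(self) -> "StateSequence":
        """Relabel Up<->Down (activity-inversion symmetry)."""
        flipped = [(s, e, UP if lab == DOWN else DOWN)
                   for s, e, lab in self.intervals]
        return StateSequence(flipped, source=self.source)

    @classmethod
    def from_labels(cls, t: np.ndarray, up_mask: np.ndarray,
                    source: str = "model") -> "StateSequence":
        """Build from a boolean per-sample Up mask on a uniform time grid."""
        t = np.asarray(t, dtype=float)
        up_mask = np.asarray(up_mask, dtype=bool)
        if len(t) != len(up_mask) or len(t) == 0:
            raise ValueError("t and up_mask must be equal-length, non-empty")
        dt = t[1] - t[0] if len(t) > 1 else 0.0
        change = np.flatnonzero(np.diff(up_mask)) + 1
        bounds = np.concatenate(([0], change, [len(t)]))
        intervals = []
        for i in range(len(bounds) - 1):
            a, b = bounds[i], bounds[i + 1]
            end = t[b] if b < len(t) else t[-1] + dt
            intervals.append((float(t[a]), float(end),
                              UP if up_mask[a] else DOWN))
        return cls(intervals, source=source)

    def sample_labels(self, t: np.ndarray) -> np.ndarray:
        """Boolean Up mask at query times (False outside the sequence)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(len(t), dtype=bool)
        for s, e, lab in self.intervals:
            if lab == UP:
                out |= (t >= s) & (t < e)
        return out

    def restrict(self, t0: float, t1: float) -> "StateSequence":
        """Clip to [t0, t1); partial boundary states are truncated."""
        out = []
        for s, e, lab in self.intervals:
            a, b = max(s, t0), min(e, t1)
            if b > a:
                out.append((a, b, lab))
        return StateSequence(out, source=self.source)


@dataclass
class EpochSet:
    """Disjoint, sorted intervals sharing one label."""

    intervals: List[Tuple[float, float]] = field(default_factory=list)
    label: str = "desynchronized"

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for (s, e) in self.intervals:
            if e <= s:
                raise ValueError(f"non-positive epoch ({s}, {e})")
            if s < prev_end:
                raise ValueError("epochs must be disjoint and sorted")
            prev_end = e

    def total_duration(self) -> float:
        return float(sum(e - s for s, e in self.intervals))

    def contains(self, t: float) -> bool:
        return any(s <= t < e for s, e in self.intervals)

    def overlap(self, t0: float, t1: float) -> float:
        """Total overlap of [t0, t1) with the epochs, in seconds."""
        return float(sum(max(0.0, min(e, t1) - max(s, t0))
                         for s, e in self.intervals))

    def complement(self, t0: float, t1: float) -> "EpochSet":
        """Intervals of [t0, t1) not covered by this set."""
        out = []
        cursor = t0
        for s, e in self.intervals:
            if s > cursor:
                out.append((cursor, min(s, t1)))
            cursor = max(cursor, e)
            if cursor >= t1:
                break
        if cursor < t1:
            out.append((cursor, t1))
        lab = "synchronized" if self.label == "desynchronized" else "desynchronized"
        return EpochSet([iv for iv in out if iv[1] > iv[0]], label=lab)
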