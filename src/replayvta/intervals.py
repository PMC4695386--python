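"""Sorted, non-overlapping half-open time intervals.

Used throughout for SPW-R events, SWS epochs, frames, and pause/run masks.
All times are seconds from session start; intervals are [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class IntervalSet:
    data: np.ndarray  # (n, 2) float, sorted by start, non-overlapping
    kind: str = "generic"

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.data, dtype=float))
        if arr.size == 0:
            arr = np.empty((0, 2))
        if arr.shape[1] != 2:
            raise ValueError("intervals must be (n, 2)")
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError("every interval needs start < end")
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        if arr.shape[0] > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError("intervals overlap")
        self.data = arr

    def __len__(self) -> int:
        return self.data.shape[0]

    def __iter__(self):
        return iter(self.data)

    @property
    def starts(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.data[:, 1] - self.data[:, 0]

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean array: is each time inside some interval."""
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.data[:, 0], t, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(t.shape, dtype=bool)
        inside[ok] = t[ok] < self.data[idx[ok], 1]
        return inside

    def which(self, times: np.ndarray) -> np.ndarray:
        """Index of the containing interval per time, -1 if outside."""
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.data[:, 0], t, side="right") - 1
        out = np.full(t.shape, -1, dtype=int)
        ok = (idx >= 0) & (t < self.data[np.clip(idx, 0, None), 1])
        out[ok] = idx[ok]
        return out

    def merge(self, gap_tol: float = 0.0, kind: str | None = None) -> "IntervalSet":
        """Merge intervals separated by gaps <= gap_tol."""
        if len(self) == 0:
            return IntervalSet(np.empty((0, 2)), kind or self.kind)
        merged = [self.data[0].copy()]
        for s, e in self.data[1:]:
            if s - merged[-1][1] <= gap_tol:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append(np.array([s, e]))
        return IntervalSet(np.array(merged), kind or self.kind)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        for s, e in self.data:
            for s2, e2 in other.data:
                lo, hi = max(s, s2), min(e, e2)
                if hi > lo:
                    out.append((lo, hi))
        return IntervalSet(np.array(out).reshape(-1, 2), self.kind)

    def complement(self, span: tuple[float, float]) -> "IntervalSet":
        lo, hi = span
        edges = [lo]
        for s, e in self.data:
            edges += [s, e]
        edges.append(hi)
        out = [
            (a, b)
            for a, b in zip(edges[::2], edges[1::2])
            if b > a
        ]
        return IntervalSet(np.array(out).reshape(-1, 2), self.kind)

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, times: np.ndarray, kind: str = "generic"
    ) -> "IntervalSet":
        """Contiguous True runs of a sample mask -> intervals.

        `times` are the sample times; an interval spans from the first True
        sample to one step past the last True sample of a run.
        """
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0 or not mask.any():
            return cls(np.empty((0, 2)), kind)
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        padded = np.concatenate([[False], mask, [False]])
        d = np.diff(padded.astype(int))
        starts = np.where(d == 1)[0]
        ends = np.where(d == -1)[0]
        arr = np.column_stack([times[starts], times[ends - 1] + dt])
        return cls(arr, kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"kind": self.kind, "start_s": self.starts, "end_s": self.ends}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalSet":
        kind = str(df["kind"].iloc[0]) if len(df) else "generic"
        return cls(df[["start_s", "end_s"]].to_numpy(dtype=float), kind)
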