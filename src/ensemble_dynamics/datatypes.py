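"""Core containers for spike-train, ethogram, LFP and epoch data.

All times are seconds, 0-based within a session; intervals are half-open
``[start, end)`` so that epoch membership is unambiguous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Behavior vocabulary, in the fixed concatenation order used throughout.
BEHAVIORS = ("feeding", "social", "object")

#: Minimum duration of a scored feeding bout (s); shorter bouts are not scored.
MIN_FEEDING_S = 4.8


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


class FormatError(ValueError):
    """Raised when a file does not match the expected dialect."""


@dataclass
class Cell:
    """One unit: identity plus its sorted spike times (s)."""

    cell_id: str
    session_id: str
    shank_id: int
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.ndim != 1:
            raise ValidationError(f"cell {self.cell_id}: spike times must be 1-D")
        if t.size and np.any(np.diff(t) < 0):
            raise ValidationError(f"cell {self.cell_id}: spike times not sorted")
        if t.size and t[0] < 0:
            raise ValidationError(f"cell {self.cell_id}: negative spike time")
        self.spike_times_s = t

    @property
    def key(self) -> tuple[str, str]:
        return (self.session_id, self.cell_id)


@dataclass
class SpikeDataset:
    """Spike trains of many cells across one or more sessions."""

    cells: list[Cell]
    session_spans: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for c in self.cells:
            if c.key in seen:
                raise ValidationError(f"duplicate cell {c.key}")
            seen.add(c.key)
            if c.session_id not in self.session_spans:
                raise ValidationError(f"cell {c.key}: unknown session")
            t0, t1 = self.session_spans[c.session_id]
            if c.spike_times_s.size and (
                c.spike_times_s[0] < t0 or c.spike_times_s[-1] >= t1
            ):
                raise ValidationError(
                    f"cell {c.key}: spikes outside session span [{t0}, {t1})"
                )

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def session_ids(self) -> list[str]:
        return sorted(self.session_spans)

    def cells_of(self, session_id: str) -> list[Cell]:
        return [c for c in self.cells if c.session_id == session_id]

    def get(self, session_id: str, cell_id: str) -> Cell:
        for c in self.cells:
            if c.session_id == session_id and c.cell_id == cell_id:
                return c
        raise KeyError((session_id, cell_id))


@dataclass
class Episode:
    session_id: str
    behavior: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValidationError(
                f"unknown behavior {self.behavior!r}; expected one of {BEHAVIORS}"
            )
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"episode {self.session_id} {self.behavior}: end must exceed start"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Ethogram:
    """Scored, non-overlapping behavioral episodes per session."""

    episodes: list[Episode]

    def __post_init__(self) -> None:
        by_sess: dict[str, list[Episode]] = {}
        for ep in self.episodes:
            if ep.behavior == "feeding" and ep.duration_s < MIN_FEEDING_S:
                raise ValidationError(
                    f"feeding episode of {ep.duration_s:.2f} s below the "
                    f"{MIN_FEEDING_S} s scoring minimum"
                )
            by_sess.setdefault(ep.session_id, []).append(ep)
        for sess, eps in by_sess.items():
            eps_sorted = sorted(eps, key=lambda e: e.start_s)
            for a, b in zip(eps_sorted, eps_sorted[1:]):
                if b.start_s < a.end_s:
                    raise ValidationError(
                        f"overlapping episodes in session {sess}: "
                        f"{a.behavior} [{a.start_s}, {a.end_s}) and "
                        f"{b.behavior} [{b.start_s}, {b.end_s})"
                    )

    def __len__(self) -> int:
        return len(self.episodes)

    def of(self, session_id: str | None = None, behavior: str | None = None) -> list[Episode]:
        out = self.episodes
        if session_id is not None:
            out = [e for e in out if e.session_id == session_id]
        if behavior is not None:
            out = [e for e in out if e.behavior == behavior]
        return sorted(out, key=lambda e: e.start_s)

    def durations(self, behavior: str) -> np.ndarray:
        return np.array([e.duration_s for e in self.episodes if e.behavior == behavior])


@dataclass
class LfpSignal:
    """Single-channel local field potential in microvolts."""

    samples: np.ndarray
    fs_hz: float
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass
class EpochSet:
    """Labeled, sorted, disjoint half-open time intervals within one session."""

    label: str
    intervals: np.ndarray  # (n, 2) seconds
    session_id: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValidationError(f"{self.label}: empty or inverted interval")
            order = np.argsort(iv[:, 0])
            iv = iv[order]
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValidationError(f"{self.label}: overlapping intervals")
        self.intervals = iv

    def __len__(self) -> int:
        return self.intervals.shape[0]

    @property
    def total_s(self) -> float:
        if not len(self):
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which of `times` fall inside any [start, end)."""
        t = np.asarray(times, dtype=float)
        if not len(self):
            return np.zeros(t.shape, dtype=bool)
        starts = self.intervals[:, 0]
        ends = self.intervals[:, 1]
        idx = np.searchsorted(starts, t, side="right") - 1
        ok = idx >= 0
        mask = np.zeros(t.shape, dtype=bool)
        mask[ok] = t[ok] < ends[idx[ok]]
        return mask

    def overlap_s(self, other: "EpochSet") -> float:
        """Total overlap duration (s) between two epoch sets."""
        tot = 0.0
        for a0, a1 in self.intervals:
            lo = np.maximum(other.intervals[:, 0], a0) if len(other) else np.array([])
            hi = np.minimum(other.intervals[:, 1], a1) if len(other) else np.array([])
            if lo.size:
                tot += float(np.sum(np.clip(hi - lo, 0.0, None)))
        return tot

    def replace(self, **kw) -> "EpochSet":
        return dataclasses.replace(self, **kw)
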