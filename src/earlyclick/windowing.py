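"""Early-window subsets and the monitored descriptives.

An early window is a prefix of a clickstream, defined either by a number of
actions w^a or by elapsed time w^t (seconds). A stream enters the w^a
subset only if its untrimmed length a_i strictly exceeds w^a (it is then
trimmed to its first w^a events); it enters the w^t subset only if its time
on task t_i strictly exceeds w^t (events with t <= w^t are retained, which
may leave zero events — such streams stay in the subset).

Per stream the two Earliness metrics measure the relative distance from the
prediction point to the end of the sequence, computed from the UNTRIMMED
length and time:

    actions mode:  earliness_actions = 1 - w^a / a_i
                   earliness_time    = 1 - t^{w^a} / t_i
    time mode:     earliness_actions = 1 - a^{w^t} / a_i
                   earliness_time    = 1 - w^t / t_i

where t^{w^a} is the timestamp of the w^a-th event and a^{w^t} the number
of events up to w^t. Utility is the fraction of all failing streams that
survive the inclusion rule; the base rate is the proportion of successes in
the subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import Clickstream

__all__ = [
    "WindowSpec",
    "EarlyWindowDataset",
    "subset_and_trim",
    "earliness",
    "utility",
    "window_grid",
    "full_dataset",
    "TASK_A_GRID",
    "TASK_B_GRID",
]


@dataclass(frozen=True)
class WindowSpec:
    """An early-window definition: by action count or elapsed seconds."""

    mode: str  # "actions" or "time"
    w: float

    def __post_init__(self) -> None:
        if self.mode not in ("actions", "time"):
            raise ValueError(f"mode must be 'actions' or 'time', got {self.mode!r}")
        if self.w <= 0:
            raise ValueError(f"window size must be positive, got {self.w}")
        if self.mode == "actions" and self.w != int(self.w):
            raise ValueError(f"actions-mode window must be an integer, got {self.w}")

    def __str__(self) -> str:
        w = int(self.w) if self.mode == "actions" else self.w
        return f"{self.mode}:{w}"


@dataclass(frozen=True)
class EarlyWindowDataset:
    """Trimmed streams for one window plus the monitored descriptives.

    ``earliness_actions`` / ``earliness_time`` are aligned per-stream
    arrays; ``utility`` is the retained fraction of all failures in the
    source collection; ``base_rate`` the proportion of successes in the
    subset. ``spec`` is None for the untrimmed full-sequence dataset.
    """

    spec: WindowSpec | None
    streams: tuple[Clickstream, ...]
    earliness_actions: np.ndarray
    earliness_time: np.ndarray
    utility: float
    base_rate: float

    @property
    def n(self) -> int:
        return len(self.streams)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.outcome for s in self.streams], dtype=int)

    def descriptives(self) -> dict:
        """Summary used in reports: utility, base rate, earliness quantiles."""
        out = {
            "window": str(self.spec) if self.spec else "full",
            "n": self.n,
            "utility": self.utility,
            "base_rate": self.base_rate,
        }
        for name, vals in (
            ("earliness_actions", self.earliness_actions),
            ("earliness_time", self.earliness_time),
        ):
            if vals.size:
                out[f"{name}_median"] = float(np.median(vals))
                out[f"{name}_q25"] = float(np.quantile(vals, 0.25))
                out[f"{name}_q75"] = float(np.quantile(vals, 0.75))
        return out


def earliness(stream: Clickstream, spec: WindowSpec) -> tuple[float, float]:
    """Both Earliness metrics for one stream satisfying the inclusion rule.

    Returns ``(earliness_actions, earliness_time)``, each in (0, 1).
    """
    a_i = stream.length
    t_i = stream.total_time
    if spec.mode == "actions":
        w = int(spec.w)
        if a_i <= w:
            raise ValueError(f"stream {stream.id!r}: a_i={a_i} does not exceed w^a={w}")
        t_w = stream.events[w - 1].t  # time required for the first w^a actions
        e_time = 1.0 - t_w / t_i if t_i > 0 else np.nan
        return 1.0 - w / a_i, e_time
    if t_i <= spec.w:
        raise ValueError(f"stream {stream.id!r}: t_i={t_i} does not exceed w^t={spec.w}")
    a_w = sum(1 for e in stream.events if e.t <= spec.w)
    return 1.0 - a_w / a_i, 1.0 - spec.w / t_i


def _trim(stream: Clickstream, spec: WindowSpec) -> Clickstream:
    if spec.mode == "actions":
        return replace(stream, events=stream.events[: int(spec.w)])
    return replace(stream, events=tuple(e for e in stream.events if e.t <= spec.w))


def subset_and_trim(streams: Sequence[Clickstream], spec: WindowSpec) -> EarlyWindowDataset:
    """Apply one window: strict inclusion, prefix trimming, descriptives.

    Earliness is computed from the untrimmed a_i and t_i before trimming.
    An empty resulting subset is an error.
    """
    if spec.mode == "actions":
        included = [s for s in streams if s.length > spec.w]
    else:
        included = [s for s in streams if s.total_time > spec.w]
    if not included:
        raise ValueError(f"window {spec} leaves an empty subset")
    e_pairs = [earliness(s, spec) for s in included]
    trimmed = tuple(_trim(s, spec) for s in included)
    n_fail_full = sum(s.outcome for s in streams)
    if n_fail_full == 0:
        raise ValueError("source collection contains no failures; utility undefined")
    n_fail_sub = sum(s.outcome for s in included)
    return EarlyWindowDataset(
        spec=spec,
        streams=trimmed,
        earliness_actions=np.array([p[0] for p in e_pairs]),
        earliness_time=np.array([p[1] for p in e_pairs]),
        utility=n_fail_sub / n_fail_full,
        base_rate=1.0 - n_fail_sub / len(included),
    )


def utility(subset: EarlyWindowDataset, full: Sequence[Clickstream]) -> float:
    """Fraction of all failing streams that survived the inclusion rule."""
    n_fail_full = sum(s.outcome for s in full)
    if n_fail_full == 0:
        raise ValueError("no failures in the full collection")
    n_fail_sub = int(subset.labels.sum())
    return n_fail_sub / n_fail_full


def window_grid(streams: Sequence[Clickstream], specs: Sequence[WindowSpec]) -> list[EarlyWindowDataset]:
    """One EarlyWindowDataset per spec, in the given order."""
    if not specs:
        raise ValueError("empty window grid")
    if len(set(specs)) != len(specs):
        warnings.warn("duplicate window specs in grid; duplicate datasets will be produced")
    return [subset_and_trim(streams, spec) for spec in specs]


def full_dataset(streams: Sequence[Clickstream]) -> EarlyWindowDataset:
    """Wrap untrimmed streams as a pseudo-window (the full-sequence baseline)."""
    streams = tuple(streams)
    if not streams:
        raise ValueError("empty collection")
    n_fail = sum(s.outcome for s in streams)
    return EarlyWindowDataset(
        spec=None,
        streams=streams,
        earliness_actions=np.array([]),
        earliness_time=np.array([]),
        utility=1.0,
        base_rate=1.0 - n_fail / len(streams),
    )


def _grid(actions: Sequence[int], times: Sequence[float]) -> list[WindowSpec]:
    return [WindowSpec("actions", w) for w in actions] + [WindowSpec("time", w) for w in times]


#: Two reference window grids (7 + 4 and 9 + 6 windows, 26 datasets in total)
#: sized for a simpler and a more complex task.
TASK_A_GRID = _grid(range(1, 8), (20, 30, 40, 50))
TASK_B_GRID = _grid(range(1, 10), (20, 30, 40, 50, 60, 70))
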