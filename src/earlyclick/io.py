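"""Reading, validating, preprocessing, and summarizing clickstream logs.

A *clickstream* is one examinee's ordered sequence of logged interface
actions with timestamps (seconds since task onset), together with a binary
outcome where 1 codes failure and 0 codes at-least-partial success.
Preprocessing applies configurable recoding and drop rules: raw actions are
collapsed into aggregate categories, score-revealing or submission actions
are removed, an initial "Start" token and a terminal proceed/confirm bigram
can be stripped, and polytomous raw scores are binarized (partial credit
counts as success).
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Event",
    "Clickstream",
    "ActionMap",
    "ScoringRule",
    "read_log",
    "write_log",
    "preprocess",
    "describe",
]


class Event(NamedTuple):
    """One logged action with its timestamp in seconds since task onset."""

    action: str
    t: float


@dataclass(frozen=True)
class Clickstream:
    """One examinee's timed action sequence plus binary outcome.

    ``outcome`` is 1 for failure and 0 for (at least partial) success —
    failure is the positive class throughout the package. ``total_time``
    is the time spent on task t_i; it must not be smaller than the last
    event's timestamp.
    """

    id: str
    events: tuple[Event, ...]
    outcome: int
    total_time: float

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError(f"stream {self.id!r}: outcome must be 0 or 1, got {self.outcome!r}")
        times = [e.t for e in self.events]
        if any(t < 0 for t in times):
            raise ValueError(f"stream {self.id!r}: negative timestamp")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"stream {self.id!r}: timestamps not non-decreasing")
        if self.events and self.total_time < times[-1] - 1e-9:
            raise ValueError(
                f"stream {self.id!r}: total_time {self.total_time} precedes last event at {times[-1]}"
            )

    @property
    def length(self) -> int:
        """Number of events a_i."""
        return len(self.events)

    @property
    def actions(self) -> tuple[str, ...]:
        return tuple(e.action for e in self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.t for e in self.events], dtype=float)


@dataclass(frozen=True)
class ActionMap:
    """Recoding and drop rules applied to raw action labels.

    ``recode`` must cover every raw label that survives the drop rules;
    unknown labels are an error, never silently passed through.
    """

    recode: Mapping[str, str] = field(default_factory=dict)
    drop_actions: frozenset[str] = frozenset()
    drop_start: bool = True
    start_label: str = "Start"
    drop_terminal_bigram: tuple[str, str] | None = None
    # Raw labels absent from `recode` keep their own name when True. None
    # resolves to lenient when no recode map is supplied, strict otherwise:
    # with an explicit map, unmapped labels are an error.
    identity_default: bool | None = None

    @property
    def lenient(self) -> bool:
        if self.identity_default is None:
            return not self.recode
        return self.identity_default


@dataclass(frozen=True)
class ScoringRule:
    """Maps raw polytomous scores to the binary outcome (1 = failure).

    Partial credit maps to success.
    """

    failure_scores: frozenset[str] = frozenset({"incorrect", "fail", "0"})
    success_scores: frozenset[str] = frozenset({"correct", "partial", "partially correct", "1", "2"})

    def binarize(self, raw: str | int) -> int:
        key = str(raw).strip().lower()
        if key in self.failure_scores:
            return 1
        if key in self.success_scores:
            return 0
        raise ValueError(f"unmapped raw score {raw!r}")


def _sorted_events(pairs: Sequence[tuple[str, float]], stream_id: str) -> tuple[Event, ...]:
    """Sort by timestamp, stable in file order for ties; warn if reordered."""
    times = [t for _, t in pairs]
    if any(t < 0 for t in times):
        raise ValueError(f"stream {stream_id!r}: negative timestamp")
    if any(b < a for a, b in zip(times, times[1:])):
        warnings.warn(f"stream {stream_id!r}: events out of timestamp order; re-sorting", stacklevel=3)
        pairs = sorted(pairs, key=lambda p: p[1])
    return tuple(Event(a, float(t)) for a, t in pairs)


def _stream_from_record(rec: dict, where: str, scoring: ScoringRule | None) -> Clickstream:
    try:
        sid = str(rec["id"])
    except KeyError:
        raise ValueError(f"{where}: record missing 'id'") from None
    if "outcome" in rec:
        outcome = int(rec["outcome"])
    elif "score" in rec:
        rule = scoring or ScoringRule()
        outcome = rule.binarize(rec["score"])
    else:
        raise ValueError(f"{where}: record {sid!r} missing 'outcome' (or raw 'score')")
    raw_events = rec.get("events", [])
    pairs = [(str(e["a"]), float(e["t"])) for e in raw_events]
    events = _sorted_events(pairs, sid)
    if "total_time" in rec and rec["total_time"] is not None:
        total_time = float(rec["total_time"])
    else:
        total_time = events[-1].t if events else 0.0
        logger.warning("stream %r: total_time missing; defaulting to last event timestamp", sid)
    return Clickstream(id=sid, events=events, outcome=outcome, total_time=total_time)


def read_log(
    path: str | Path,
    format: str = "jsonl",
    scoring: ScoringRule | None = None,
) -> list[Clickstream]:
    """Read a clickstream collection from JSON-Lines or long CSV.

    JSON-Lines: one object per stream,
    ``{"id": ..., "outcome": 0|1, "events": [{"a": ..., "t": ...}, ...],
    "total_time": ...}``; a raw ``"score"`` may replace ``"outcome"`` and is
    binarized via ``scoring``. Long CSV: columns
    ``id, action, t, outcome[, total_time]``, one row per event.

    Events are sorted by timestamp with stable tie order as in the file.
    Duplicate ids are a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        streams = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed JSON record: {exc}") from exc
                streams.append(_stream_from_record(rec, f"{path}:{lineno}", scoring))
    elif format == "long_csv":
        df = pd.read_csv(path, dtype={"id": str, "action": str})
        required = {"id", "action", "t", "outcome"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: long CSV missing columns {sorted(missing)}")
        streams = []
        for sid, grp in df.groupby("id", sort=False):
            outcome = int(grp["outcome"].iloc[0])
            pairs = list(zip(grp["action"], grp["t"].astype(float)))
            events = _sorted_events(pairs, str(sid))
            if "total_time" in grp.columns and not pd.isna(grp["total_time"].iloc[0]):
                total_time = float(grp["total_time"].iloc[0])
            else:
                total_time = events[-1].t if events else 0.0
                logger.warning("stream %r: total_time missing; defaulting to last event timestamp", sid)
            streams.append(Clickstream(id=str(sid), events=events, outcome=outcome, total_time=total_time))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'long_csv'")

    ids = [s.id for s in streams]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate stream ids {dupes}")
    return streams


def write_log(streams: Iterable[Clickstream], path: str | Path, format: str = "jsonl") -> None:
    """Write a clickstream collection in either supported format."""
    path = Path(path)
    streams = list(streams)
    if format == "jsonl":
        with open(path, "w") as fh:
            for s in streams:
                rec = {
                    "id": s.id,
                    "outcome": s.outcome,
                    "events": [{"a": e.action, "t": round(e.t, 3)} for e in s.events],
                    "total_time": round(s.total_time, 3),
                }
                fh.write(json.dumps(rec) + "\n")
    elif format == "long_csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "action", "t", "outcome", "total_time"])
            for s in streams:
                for e in s.events:
                    writer.writerow([s.id, e.action, round(e.t, 3), s.outcome, round(s.total_time, 3)])
    else:
        raise ValueError(f"unknown format {format!r}")


def _apply_map(stream: Clickstream, amap: ActionMap) -> Clickstream:
    events = list(stream.events)
    if amap.drop_start:
        events = [e for e in events if e.action != amap.start_label]
    if amap.drop_terminal_bigram is not None and len(events) >= 2:
        a, b = amap.drop_terminal_bigram
        if events[-2].action == a and events[-1].action == b:
            events = events[:-2]
    events = [e for e in events if e.action not in amap.drop_actions]
    # recode targets pass through unchanged, which keeps preprocess idempotent
    known = set(amap.recode) | set(amap.recode.values())
    unmapped = [] if amap.lenient else sorted({e.action for e in events} - known)
    if unmapped:
        raise ValueError(f"stream {stream.id!r}: unmapped raw labels {unmapped}")
    recoded = tuple(Event(amap.recode.get(e.action, e.action), e.t) for e in events)
    return replace(stream, events=recoded)


def preprocess(
    streams: Iterable[Clickstream],
    action_map: ActionMap | None = None,
    scoring: ScoringRule | None = None,
) -> list[Clickstream]:
    """Recode labels, apply drop rules, and exclude zero-action streams.

    Outcomes are assumed already binary at this point (raw scores are
    binarized on read); ``scoring`` is accepted for symmetry and applied to
    nothing unless a stream carries a non-binary outcome, which is an error
    upstream. Streams left with zero events after the drop rules — e.g. a
    lone "Start" token — are removed, matching the exclusion of examinees
    who proceeded without performing any actions. Idempotent.
    """
    amap = action_map or ActionMap()
    out = []
    for s in streams:
        cleaned = _apply_map(s, amap)
        if cleaned.length >= 1:
            out.append(cleaned)
    return out


def describe(streams: Sequence[Clickstream]) -> dict[str, pd.DataFrame]:
    """Summarize a collection per action and per outcome group.

    Returns ``{"actions": ..., "groups": ...}``. The actions table gives,
    per action and group, the sequence frequency (proportion of streams
    containing the action at least once), the action frequency (total
    occurrence count in the group), and the median time to first
    occurrence. The groups table gives the median and middle-50% range
    (quartiles) of sequence length and time on task per group.
    """
    if not streams:
        raise ValueError("describe requires a non-empty collection")
    rows = []
    group_names = {1: "failure", 0: "success"}
    for outcome, gname in group_names.items():
        grp = [s for s in streams if s.outcome == outcome]
        if not grp:
            continue
        vocab = sorted({a for s in grp for a in s.actions})
        for action in vocab:
            containing = [s for s in grp if action in s.actions]
            firsts = [next(e.t for e in s.events if e.action == action) for s in containing]
            rows.append(
                {
                    "action": action,
                    "group": gname,
                    "sequence_frequency": len(containing) / len(grp),
                    "action_frequency": sum(s.actions.count(action) for s in grp),
                    "median_time_to_first": float(np.median(firsts)) if firsts else np.nan,
                }
            )
    actions = pd.DataFrame(rows)

    grows = []
    for outcome, gname in group_names.items():
        grp = [s for s in streams if s.outcome == outcome]
        if not grp:
            continue
        lengths = np.array([s.length for s in grp])
        times = np.array([s.total_time for s in grp])
        grows.append(
            {
                "group": gname,
                "n": len(grp),
                "length_median": float(np.median(lengths)),
                "length_q25": float(np.quantile(lengths, 0.25)),
                "length_q75": float(np.quantile(lengths, 0.75)),
                "time_median": float(np.median(times)),
                "time_q25": float(np.quantile(times, 0.25)),
                "time_q75": float(np.quantile(times, 0.75)),
            }
        )
    return {"actions": actions, "groups": pd.DataFrame(grows)}
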