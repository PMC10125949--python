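"""Feature construction for early-window clickstreams.

Five feature families are built from a trimmed early-window dataset:

* ``first_action_time`` — timestamp of the first event (planning time);
  missing for zero-event trimmed streams.
* ``<action>_tfidf`` — term-frequency–inverse-document-frequency weight of
  each action, with natural logarithms:
  ``(1 + ln tf) * ln(N / df)`` when the action occurs ``tf >= 1`` times in
  the stream, 0 when absent. ``df`` is the number of scope sequences
  containing the action, ``N`` the number of scope sequences.
* ``<action>_T`` — time to the action's first occurrence; missing when the
  action does not occur in the stream.
* ``ngram:<a|b|...>`` — one-hot indicators for contiguous bigrams and
  trigrams of action labels (presence only, never counts). Unigram one-hot
  columns are deliberately not built: their information is already carried
  by the tf-idf and time-to-first-occurrence columns.
* ``activity`` — time elapsed inside the window when trimming by actions,
  number of performed actions when trimming by time.

The scope over which df, N, the action vocabulary and the n-gram vocabulary
are computed is configurable: ``"subset"`` uses the full early-window
dataset; ``"train"`` restricts them to a training partition so held-out
rows are featurized without leakage (fit on train, transform anything).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Clickstream
from .windowing import EarlyWindowDataset, WindowSpec

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "FeatureExtractor",
    "tfidf_weight",
    "time_to_first_action",
    "time_to_first_occurrence",
    "extract_ngrams",
    "activity",
    "build_features",
]

FAMILIES = ("first_action_time", "tfidf", "time_to_first", "ngrams", "activity")


@dataclass(frozen=True)
class FeatureConfig:
    """Which families to build and over which scope to compute statistics."""

    ngram_orders: tuple[int, ...] = (2, 3)
    idf_scope: str = "subset"  # or "train"
    families: tuple[str, ...] = FAMILIES

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one feature family must be enabled")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families {sorted(unknown)}")
        if self.idf_scope not in ("subset", "train"):
            raise ValueError(f"idf_scope must be 'subset' or 'train', got {self.idf_scope!r}")
        if not set(self.ngram_orders) <= {2, 3}:
            raise ValueError(f"ngram orders limited to 2 and 3, got {self.ngram_orders}")


@dataclass(frozen=True)
class FeatureMatrix:
    """Named numeric feature columns with an aligned binary label vector.

    Missing values (NaN) occur only in the time-to-first-occurrence and
    first-action-time columns; they are meaningful (action absent / no
    events yet) and are consumed natively by the tree learner.
    """

    X: pd.DataFrame
    y: np.ndarray
    families: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out["outcome"] = self.y
        out.to_csv(path, index_label="id", na_rep="")


def tfidf_weight(tf: int, df: int, N: int) -> float:
    """tf-idf weight of one action in one sequence (natural logarithms).

    ``(1 + ln tf) * ln(N/df)`` for ``tf >= 1``; 0 for ``tf = 0``.
    """
    if df <= 0 or df > N:
        raise ValueError(f"document frequency must satisfy 0 < df <= N, got df={df}, N={N}")
    if tf < 0:
        raise ValueError(f"term frequency must be non-negative, got {tf}")
    if tf == 0:
        return 0.0
    return (1.0 + math.log(tf)) * math.log(N / df)


def time_to_first_action(stream: Clickstream) -> float:
    """Timestamp of the first event; NaN for a zero-event trimmed stream."""
    return stream.events[0].t if stream.events else math.nan


def time_to_first_occurrence(stream: Clickstream, action: str, vocabulary: Sequence[str] | None = None) -> float:
    """Timestamp of the action's earliest occurrence; NaN when absent."""
    if vocabulary is not None and action not in vocabulary:
        raise ValueError(f"action {action!r} not in vocabulary")
    for e in stream.events:
        if e.action == action:
            return e.t
    return math.nan


def extract_ngrams(stream: Clickstream, n: int) -> set[tuple[str, ...]]:
    """Deduplicated contiguous n-tuples of action labels (n in {2, 3})."""
    if n not in (2, 3):
        raise ValueError(f"n must be 2 or 3, got {n}")
    acts = stream.actions
    return {acts[i : i + n] for i in range(len(acts) - n + 1)}


def activity(stream: Clickstream, spec: WindowSpec | None) -> float:
    """Interaction intensity inside the window.

    Actions mode (and the full-sequence baseline): timestamp of the last
    retained event, i.e. the time elapsed while performing the retained
    actions (0 for an empty stream). Time mode: the number of retained
    events.
    """
    if spec is not None and spec.mode == "time":
        return float(stream.length)
    return stream.events[-1].t if stream.events else 0.0


class FeatureExtractor:
    """Fit vocabulary and document statistics on a scope; transform streams.

    ``fit`` learns the action vocabulary, per-action document frequencies,
    the scope size N, and the observed n-gram vocabulary. ``transform``
    featurizes any stream collection using only the fitted statistics, so
    fitting on a training partition keeps held-out rows leakage-free.
    N-grams unseen in the scope are dropped, not zero-columns.
    """

    def __init__(self, config: FeatureConfig | None = None, spec: WindowSpec | None = None):
        self.config = config or FeatureConfig()
        self.spec = spec
        self.vocabulary_: list[str] | None = None
        self.df_: dict[str, int] | None = None
        self.N_: int | None = None
        self.ngram_vocab_: list[tuple[str, ...]] | None = None

    def fit(self, streams: Sequence[Clickstream]) -> "FeatureExtractor":
        self.N_ = len(streams)
        self.df_ = Counter()
        for s in streams:
            for action in set(s.actions):
                self.df_[action] += 1
        self.vocabulary_ = sorted(self.df_)
        ngrams = set()
        if "ngrams" in self.config.families:
            for s in streams:
                for n in self.config.ngram_orders:
                    ngrams |= extract_ngrams(s, n)
        self.ngram_vocab_ = sorted(ngrams)
        return self

    def transform(self, streams: Sequence[Clickstream]) -> pd.DataFrame:
        if self.vocabulary_ is None:
            raise RuntimeError("extractor is not fitted")
        cfg = self.config
        cols: dict[str, list[float]] = {}
        if "first_action_time" in cfg.families:
            cols["first_action_time"] = [time_to_first_action(s) for s in streams]
        if "tfidf" in cfg.families:
            for action in self.vocabulary_:
                df, N = self.df_[action], self.N_
                cols[f"{action}_tfidf"] = [
                    tfidf_weight(s.actions.count(action), df, N) for s in streams
                ]
        if "time_to_first" in cfg.families:
            for action in self.vocabulary_:
                cols[f"{action}_T"] = [time_to_first_occurrence(s, action) for s in streams]
        if "ngrams" in cfg.families:
            stream_grams = [
                set().union(*(extract_ngrams(s, n) for n in cfg.ngram_orders)) for s in streams
            ]
            for gram in self.ngram_vocab_:
                cols["ngram:" + "|".join(gram)] = [
                    1.0 if gram in grams else 0.0 for grams in stream_grams
                ]
        if "activity" in cfg.families:
            cols["activity"] = [activity(s, self.spec) for s in streams]
        return pd.DataFrame(cols, index=[s.id for s in streams], dtype=float)


def build_features(dataset: EarlyWindowDataset, config: FeatureConfig | None = None) -> FeatureMatrix:
    """Build the feature matrix for one early-window dataset.

    With the default ``idf_scope="subset"`` the document statistics and the
    n-gram vocabulary are computed over the whole dataset. With
    ``idf_scope="train"`` this function still fits on the whole dataset
    (there is no split here); per-fold refitting happens in the nested-CV
    driver, which uses :class:`FeatureExtractor` directly.
    """
    config = config or FeatureConfig()
    if dataset.n == 0:
        raise ValueError("empty dataset")
    extractor = FeatureExtractor(config, dataset.spec).fit(dataset.streams)
    X = extractor.transform(dataset.streams)
    families = {
        "first_action_time": ["first_action_time"] if "first_action_time" in config.families else [],
        "tfidf": [c for c in X.columns if c.endswith("_tfidf")],
        "time_to_first": [c for c in X.columns if c.endswith("_T")],
        "ngrams": [c for c in X.columns if c.startswith("ngram:")],
        "activity": ["activity"] if "activity" in config.families else [],
    }
    return FeatureMatrix(X=X, y=dataset.labels, families=families)
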