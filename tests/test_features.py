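import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from earlyclick.features import (
    FeatureConfig,
    FeatureExtractor,
    activity,
    build_features,
    extract_ngrams,
    tfidf_weight,
    time_to_first_action,
    time_to_first_occurrence,
)
from earlyclick.windowing import WindowSpec, full_dataset, subset_and_trim
from conftest import make_stream


class TestTfidfWeight:
    def test_worked_examples(self):
        assert round(tfidf_weight(3, 300, 500), 2) == 1.07
        assert round(tfidf_weight(3, 100, 500), 2) == 3.38

    def test_zero_tf_and_saturated_df(self):
        assert tfidf_weight(0, 10, 100) == 0.0
        assert tfidf_weight(1, 100, 100) == 0.0  # ln(1) twice

    @pytest.mark.parametrize("tf,df,N", [(1, 0, 10), (1, 11, 10), (-1, 5, 10)])
    def test_invalid_inputs(self, tf, df, N):
        with pytest.raises(ValueError):
            tfidf_weight(tf, df, N)

    @given(tf=st.integers(1, 50), df=st.integers(1, 100), N=st.integers(1, 100))
    @settings(max_examples=50, derandomize=True)
    def test_non_negative_when_valid(self, tf, df, N):
        if df > N:
            return
        assert tfidf_weight(tf, df, N) >= 0.0


class TestTimingFeatures:
    def test_time_to_first_action(self):
        assert time_to_first_action(make_stream("x", ["A", "B"], [12.5, 20])) == 12.5
        assert time_to_first_action(make_stream("x", ["A"], [0])) == 0
        empty = make_stream("x", [], [], total_time=5)
        assert math.isnan(time_to_first_action(empty))

    def test_time_to_first_occurrence(self):
        s = make_stream("x", ["A", "B", "B"], [5, 30, 55])
        assert time_to_first_occurrence(s, "B") == 30
        assert math.isnan(time_to_first_occurrence(s, "Z"))
        assert time_to_first_occurrence(s, "A") == time_to_first_action(s)

    def test_unknown_action_outside_vocabulary_is_error(self):
        s = make_stream("x", ["A"], [5])
        with pytest.raises(ValueError):
            time_to_first_occurrence(s, "Z", vocabulary=["A", "B"])


class TestNgrams:
    def test_bigrams(self):
        s = make_stream("x", ["A", "B", "C"], [1, 2, 3])
        assert extract_ngrams(s, 2) == {("A", "B"), ("B", "C")}

    def test_presence_only_no_counts(self):
        s = make_stream("x", ["A", "B", "A", "B"], [1, 2, 3, 4])
        assert extract_ngrams(s, 2) == {("A", "B"), ("B", "A")}

    def test_short_stream_yields_empty(self):
        assert extract_ngrams(make_stream("x", ["A"], [1]), 3) == set()

    @given(st.lists(st.sampled_from("ABCD"), max_size=12), st.sampled_from([2, 3]))
    @settings(max_examples=50, derandomize=True)
    def test_all_grams_contiguous_and_bounded(self, actions, n):
        s = make_stream("x", actions, list(range(len(actions))))
        grams = extract_ngrams(s, n)
        assert len(grams) <= max(0, len(actions) - n + 1)
        joined = "".join(actions)
        assert all("".join(g) in joined for g in grams)


class TestActivity:
    def test_actions_mode_last_timestamp(self):
        s = make_stream("x", ["A", "B", "C"], [5, 9, 14])
        assert activity(s, WindowSpec("actions", 3)) == 14

    def test_time_mode_event_count(self):
        s = make_stream("x", list("ABCDEF"), [1, 5, 9, 14, 20, 28])
        assert activity(s, WindowSpec("time", 30)) == 6

    def test_zero_event_stream(self):
        empty = make_stream("x", [], [], total_time=50)
        assert activity(empty, WindowSpec("time", 30)) == 0
        assert activity(empty, WindowSpec("actions", 3)) == 0


class TestBuildFeatures:
    def test_column_accounting_bigrams_only(self):
        streams = [
            make_stream("a", ["A", "B"], [1, 2], outcome=1, total_time=3),
            make_stream("b", ["B", "A"], [1, 4], outcome=0, total_time=5),
        ]
        fm = build_features(full_dataset(streams), FeatureConfig(ngram_orders=(2,)))
        expected = {"first_action_time", "A_tfidf", "B_tfidf", "A_T", "B_T",
                    "ngram:A|B", "ngram:B|A", "activity"}
        assert set(fm.X.columns) == expected
        assert list(fm.y) == [1, 0]

    def test_absent_action_tfidf_zero_and_time_missing(self):
        streams = [
            make_stream("a", ["A"], [1], outcome=1, total_time=2),
            make_stream("b", ["A", "B"], [1, 2], outcome=0, total_time=3),
        ]
        fm = build_features(full_dataset(streams), FeatureConfig(ngram_orders=(2,)))
        assert fm.X.loc["a", "B_tfidf"] == 0.0
        assert math.isnan(fm.X.loc["a", "B_T"])

    def test_tfidf_matches_bruteforce_counting(self, paper_like_streams):
        ds = subset_and_trim(paper_like_streams[:120], WindowSpec("actions", 5))
        fm = build_features(ds)
        N = ds.n
        vocab = sorted({a for s in ds.streams for a in s.actions})
        df = Counter(a for s in ds.streams for a in set(s.actions))
        for s in ds.streams[:50]:
            for action in vocab:
                tf = s.actions.count(action)
                expect = 0.0 if tf == 0 else (1 + math.log(tf)) * math.log(N / df[action])
                assert fm.X.loc[s.id, f"{action}_tfidf"] == pytest.approx(expect)

    def test_tfidf_positive_iff_time_present(self, paper_like_streams):
        ds = subset_and_trim(paper_like_streams[:100], WindowSpec("actions", 4))
        fm = build_features(ds)
        N = ds.n
        df = Counter(a for s in ds.streams for a in set(s.actions))
        for col in fm.families["tfidf"]:
            action = col[: -len("_tfidf")]
            if df[action] == N:
                continue  # saturated df: weight 0 even when present
            present = fm.X[f"{action}_T"].notna()
            assert ((fm.X[col] > 0) == present).all()

    def test_row_order_invariance(self, paper_like_streams):
        ds = subset_and_trim(paper_like_streams[:80], WindowSpec("actions", 4))
        fm = build_features(ds)
        reversed_ds = subset_and_trim(paper_like_streams[:80][::-1], WindowSpec("actions", 4))
        fm_rev = build_features(reversed_ds)
        aligned = fm_rev.X.loc[fm.X.index, fm.X.columns]
        assert fm.X.equals(aligned)

    def test_no_family_enabled_is_error(self):
        with pytest.raises(ValueError):
            FeatureConfig(families=())

    def test_zero_event_stream_gets_defaults(self):
        late = make_stream("late", ["A"], [45], outcome=1, total_time=50)
        other = make_stream("o", ["A", "B"], [5, 10], outcome=0, total_time=40)
        ds = subset_and_trim([late, other], WindowSpec("time", 30))
        fm = build_features(ds, FeatureConfig(ngram_orders=(2,)))
        row = fm.X.loc["late"]
        assert (row[fm.families["tfidf"]] == 0).all()
        assert row[fm.families["time_to_first"]].isna().all()
        assert math.isnan(row["first_action_time"])
        assert row["activity"] == 0


class TestTrainScope:
    def test_heldout_features_use_only_training_statistics(self, paper_like_streams):
        streams = subset_and_trim(paper_like_streams[:150], WindowSpec("actions", 6)).streams
        train, test = list(streams[:100]), list(streams[100:])
        config = FeatureConfig(idf_scope="train")
        ex = FeatureExtractor(config).fit(train)
        X_test = ex.transform(test)
        # ngram vocabulary comes from train only
        train_grams = {c for c in ex.transform(train).columns if c.startswith("ngram:")}
        assert {c for c in X_test.columns if c.startswith("ngram:")} == train_grams
        # recomputation audit: removing held-out rows changes nothing for train rows
        ex2 = FeatureExtractor(config).fit(train)
        assert ex.transform(train).equals(ex2.transform(train))
        # df/N audit: tf-idf of a test row recomputed from train counts
        N = len(train)
        df = Counter(a for s in train for a in set(s.actions))
        s = test[0]
        for action in ex.vocabulary_:
            tf = s.actions.count(action)
            expect = 0.0 if tf == 0 else (1 + math.log(tf)) * math.log(N / df[action])
            assert X_test.loc[s.id, f"{action}_tfidf"] == pytest.approx(expect)

    def test_serialized_missing_survives_round_trip(self, tmp_path, paper_like_streams):
        ds = subset_and_trim(paper_like_streams[:60], WindowSpec("time", 25))
        fm = build_features(ds, FeatureConfig(ngram_orders=(2,)))
        p = tmp_path / "fm.csv"
        fm.to_csv(p)
        import pandas as pd

        back = pd.read_csv(p, index_col="id")
        t_cols = fm.families["time_to_first"]
        assert back[t_cols].isna().equals(fm.X[t_cols].isna())
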