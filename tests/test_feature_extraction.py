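import math

import numpy as np
import pytest

from conftest import make_session
from fluency2ef.feature_extraction import (
    CLASSICAL_FEATURES,
    FEATURE_NAMES,
    build_feature_table,
    classical_subset,
    extract_error_counts,
    extract_latencies,
    extract_semantic_means,
    extract_sum_scores,
    feature_schema,
)
from fluency2ef.session_data import FluencySession, Token


class StubBackend:
    """Fixture backend with hand-set pairwise similarities."""

    def __init__(self, sims):
        self.sims = sims

    def word_similarity(self, w1, w2):
        if w1 == w2:
            return 1.0
        return self.sims.get((w1, w2), self.sims.get((w2, w1)))


def _sessions_with_sums(s1, s2, s3):
    out = {}
    for task, n in zip(("t1", "t2", "t3"), (s1, s2, s3)):
        words = [(f"w{i}", 1.0 + 2 * i, 1.5 + 2 * i) for i in range(n)]
        out[task] = make_session(words, task_id=task)
    return out


class TestSumScores:
    def test_formula_with_equal_halves(self):
        feats = extract_sum_scores(_sessions_with_sums(20, 10, 15))
        assert feats["sum_total"] == 45
        assert feats["switch_coef"] == pytest.approx(1.0)

    def test_only_correct_tokens_counted(self):
        words = [("a", 1, 1.5), ("b", 2, 2.5), ("c", 3, 3.5),
                 ("d", 4, 4.5), ("e", 5, 5.5), ("a", 6, 6.5), ("b", 7, 7.5)]
        codes = ["correct"] * 5 + ["repetition_error"] * 2
        sessions = {"t1": make_session(words, codes=codes)}
        assert extract_sum_scores(sessions)["sum_t1"] == 5

    def test_switch_coefficient_guard(self):
        feats = extract_sum_scores(_sessions_with_sums(0, 0, 4))
        assert math.isnan(feats["switch_coef"])
        assert feats["sum_total"] == 4


class TestErrorCounts:
    def test_switching_task_error_split(self):
        words = [("a", 1, 1.5), ("b", 2, 2.5), ("c", 3, 3.5), ("d", 4, 4.5)]
        codes = ["correct", "repetition_error", "category_error", "correct"]
        cats = ["sports"] * 4
        sessions = {"t3": make_session(words, task_id="t3", codes=codes,
                                       categories=cats)}
        feats = extract_error_counts(sessions)
        assert feats["err_rep_t3"] == 1
        assert feats["err_cat_t3"] == 1

    def test_error_free_participant_is_all_zero(self):
        feats = extract_error_counts(_sessions_with_sums(3, 3, 3))
        assert feats["err_rep_t1"] == feats["err_rep_t2"] == 0
        assert feats["err_rep_t3"] == feats["err_cat_t3"] == 0

    def test_missing_task_propagates_missingness(self):
        sessions = _sessions_with_sums(3, 3, 3)
        del sessions["t3"]
        feats = extract_error_counts(sessions)
        assert math.isnan(feats["err_rep_t3"]) and math.isnan(feats["err_cat_t3"])


class TestLatencies:
    def test_single_pause_in_first_interval(self):
        session = make_session([("dog", 1.0, 1.5), ("cat", 3.5, 4.0)])
        prof = extract_latencies(session)
        assert prof.pauses == [pytest.approx(2.0)]
        assert prof.intervals[0] == pytest.approx(2.0)
        assert all(math.isnan(v) for v in prof.intervals[1:])
        assert prof.mean == pytest.approx(2.0)
        assert math.isnan(prof.difference)

    def test_interval_assignment_by_pause_start_and_difference(self):
        # 1.0 s pause starting at 10 s; 3.0 s pause starting at 100 s
        session = make_session(
            [("a", 5.0, 10.0), ("b", 11.0, 99.0), ("c", 102.0, 103.0)],
        )
        prof = extract_latencies(session)
        assert prof.intervals[0] == pytest.approx(1.0)
        assert prof.intervals[3] == pytest.approx(3.0)
        assert prof.difference == pytest.approx(2.0)

    def test_single_token_has_no_pauses(self):
        prof = extract_latencies(make_session([("dog", 1.0, 1.5)]))
        assert prof.pauses == []
        assert math.isnan(prof.mean) and math.isnan(prof.difference)

    def test_pauses_include_error_tokens_by_default(self):
        session = make_session(
            [("a", 1.0, 1.5), ("b", 3.0, 3.5), ("c", 5.0, 5.5)],
            codes=["correct", "repetition_error", "correct"],
        )
        assert len(extract_latencies(session).pauses) == 2
        assert len(extract_latencies(session, tokens="correct").pauses) == 1


class TestSemanticMeans:
    def test_sequential_and_cumulative_hand_values(self):
        backend = StubBackend({("w1", "w2"): 0.9, ("w2", "w3"): 0.8,
                               ("w1", "w3"): 0.7})
        session = make_session([("w1", 1, 1.5), ("w2", 2, 2.5), ("w3", 3, 3.5)])
        out = extract_semantic_means(session, backend)
        assert out["sequential"] == pytest.approx((0.9 + 0.8) / 2)
        assert out["cumulative"] == pytest.approx((0.9 + 0.8 + 0.7) / 3)

    def test_missing_word_deletes_pairs_without_splicing(self):
        # w2 unknown: both consecutive pairs die (neighbours are not joined);
        # the cumulative (w1, w3) pair survives.
        backend = StubBackend({("w1", "w3"): 0.7})
        session = make_session([("w1", 1, 1.5), ("w2", 2, 2.5), ("w3", 3, 3.5)])
        out = extract_semantic_means(session, backend)
        assert math.isnan(out["sequential"])
        assert out["cumulative"] == pytest.approx(0.7)

    def test_strict_alternation_leaves_category_means_undefined(self):
        backend = StubBackend({("s1", "f1"): 0.3, ("f1", "s2"): 0.4,
                               ("s1", "s2"): 0.9})
        session = make_session(
            [("s1", 1, 1.5), ("f1", 2, 2.5), ("s2", 3, 3.5)],
            task_id="t3",
            categories=["sports", "fruits", "sports"],
        )
        out = extract_semantic_means(session, backend)
        assert math.isnan(out["sequential_cat1"])
        assert math.isnan(out["sequential_cat2"])
        assert out["sequential"] == pytest.approx(0.35)

    def test_within_category_consecutive_pairs_only(self):
        backend = StubBackend({("s1", "s2"): 0.9, ("s2", "f1"): 0.2,
                               ("f1", "f2"): 0.6, ("s1", "f1"): 0.1,
                               ("s1", "f2"): 0.1, ("s2", "f2"): 0.1})
        session = make_session(
            [("s1", 1, 1.5), ("s2", 2, 2.5), ("f1", 3, 3.5), ("f2", 4, 4.5)],
            task_id="t3",
            categories=["sports", "sports", "fruits", "fruits"],
        )
        out = extract_semantic_means(session, backend)
        assert out["sequential_cat1"] == pytest.approx(0.9)
        assert out["sequential_cat2"] == pytest.approx(0.6)


class TestFeatureTable:
    def test_exactly_43_features_and_4_classical(self, small_cohort, taxonomy,
                                                 embeddings):
        table = build_feature_table(small_cohort.sessions, taxonomy, embeddings)
        assert table.shape[1] == len(FEATURE_NAMES) == 43
        assert classical_subset(table).shape[1] == len(CLASSICAL_FEATURES) == 4
        assert set(feature_schema()) == set(FEATURE_NAMES)

    def test_participant_with_only_t1(self, taxonomy, embeddings):
        session = make_session([("dog", 1, 1.5), ("cat", 3, 3.5)])
        table = build_feature_table([session], taxonomy, embeddings)
        row = table.iloc[0]
        assert row["sum_t1"] == 2
        assert not math.isnan(row["sem_seq_tax_t1"])
        for col in ("sum_t2", "sum_t3", "sum_total", "switch_coef",
                    "err_rep_t2", "lat_mean_t3", "sem_cum_emb_t2"):
            assert math.isnan(row[col])

    def test_sum_total_is_sum_of_parts(self, small_cohort, taxonomy, embeddings):
        table = build_feature_table(small_cohort.sessions, taxonomy, embeddings)
        complete = table.dropna(subset=["sum_t1", "sum_t2", "sum_t3"])
        np.testing.assert_allclose(
            complete["sum_total"],
            complete[["sum_t1", "sum_t2", "sum_t3"]].sum(axis=1),
        )

    def test_latency_features_nonnegative_except_difference(self, small_cohort):
        table = build_feature_table(small_cohort.sessions)
        lat_cols = [c for c in table.columns
                    if c.startswith("lat_") and "diff" not in c]
        assert (table[lat_cols].min() >= 0).all()

    def test_missing_backend_leaves_backend_columns_missing(self, small_cohort,
                                                            taxonomy):
        table = build_feature_table(small_cohort.sessions, taxonomy, None)
        emb_cols = [c for c in table.columns if "_emb_" in c]
        assert table[emb_cols].isna().all().all()
        assert table["sem_seq_tax_t1"].notna().any()

    def test_permutation_invariance_of_cumulative_mean(self, taxonomy):
        rng = np.random.default_rng(11)
        words = ["dog", "cat", "lion", "cow", "eagle", "shark"]
        times = [(1.0 + 3 * i, 2.0 + 3 * i) for i in range(len(words))]

        def session_for(order):
            return make_session([(words[j], *times[i])
                                 for i, j in enumerate(order)])

        base = extract_semantic_means(session_for(range(len(words))), taxonomy)
        for _ in range(5):
            perm = rng.permutation(len(words))
            out = extract_semantic_means(session_for(perm), taxonomy)
            assert out["cumulative"] == pytest.approx(base["cumulative"])

        # swapping two non-consecutive words changes the sequential mean here
        swapped = list(range(len(words)))
        swapped[0], swapped[3] = swapped[3], swapped[0]
        out = extract_semantic_means(session_for(swapped), taxonomy)
        assert out["sequential"] != pytest.approx(base["sequential"])
        assert out["cumulative"] == pytest.approx(base["cumulative"])

    def test_duplicate_session_rejected(self):
        s = make_session([("dog", 1, 1.5)])
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table([s, s])
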