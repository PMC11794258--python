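import numpy as np
import pytest
from scipy import stats

from twotk.core import ActType
from twotk.metrics import (
    MetricPoint,
    MetricSeries,
    UndefinedMetricError,
    act_type_profile,
    celerity,
    per_concatenation_metrics,
    primacy_check,
    running_vergence,
    slowdown,
    vc_correlation,
    vergence,
)


class TestVergenceCelerity:
    def test_fixture_whole_dialogue(self, monte_cristo):
        acts = monte_cristo.acts()
        assert vergence(acts, "task") == 1.0
        assert celerity(acts) == 0.75
        assert slowdown(acts) == 25.0

    @pytest.mark.parametrize(
        "deltas,expected",
        [([1, 1, 1, 0, 0], 0.6), ([0, 0, 0], 0.0), ([1], 1.0)],
    )
    def test_vergence_arithmetic(self, make_acts, deltas, expected):
        acts = make_acts([(d, 0) for d in deltas])
        assert vergence(acts, "task") == pytest.approx(expected)

    def test_celerity_all_decisive(self, make_acts):
        acts = make_acts([(1, 1)] * 4)
        assert celerity(acts) == 1.0

    def test_empty_set_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            vergence([], "task")
        with pytest.raises(UndefinedMetricError):
            celerity([])

    def test_missing_polarity_annotation_raises(self, make_acts):
        acts = make_acts([(1, 0)])
        with pytest.raises(KeyError, match="nonexistent"):
            vergence(acts, "nonexistent")

    def test_vergence_invariant_to_act_order(self, random_dialogue):
        acts = random_dialogue(3, p_delta_task=0.5).acts()
        shuffled = list(reversed(acts))
        assert vergence(acts, "task") == vergence(shuffled, "task")


class TestPerConcatenation:
    def test_fixture_both_themes_fully_convergent(self, monte_cristo):
        series = per_concatenation_metrics(monte_cristo, "task")
        assert [p.vergence for p in series] == [1.0, 1.0]
        assert [p.n_acts for p in series] == [6, 2]

    def test_null_polarity_concatenation_scores_zero(self, random_dialogue):
        d = random_dialogue(1, n_concatenations=2, p_delta_task=0.0)
        series = per_concatenation_metrics(d, "task")
        assert all(p.vergence == 0.0 for p in series)

    @pytest.mark.parametrize("seed", range(10))
    def test_primacy_pointwise_on_synthetic(self, random_dialogue, seed):
        series = per_concatenation_metrics(random_dialogue(seed), "task")
        assert all(p.celerity <= p.vergence for p in series)


class TestRunningVergence:
    def test_constant_positive_stream(self, make_acts):
        from twotk.core import build_dialogue

        d = build_dialogue(make_acts([(1, 0)] * 12), participants=["A", "B"])
        for window in (1, 3, "cumulative"):
            series = running_vergence(d, window=window)
            assert all(p.vergence == 1.0 for p in series)

    def test_alternating_stream_window_two(self, make_acts):
        from twotk.core import build_dialogue

        d = build_dialogue(make_acts([(i % 2, 0) for i in range(1, 11)]),
                           participants=["A", "B"])
        series = running_vergence(d, window=2)
        assert all(p.vergence == 0.5 for p in list(series)[1:])

    @pytest.mark.parametrize("window", [1, 3, 7, 20])
    def test_matches_brute_force_recount(self, random_dialogue, window):
        d = random_dialogue(7, n_concatenations=4, p_delta_task=0.5)
        acts = d.acts()
        series = running_vergence(d, window=window)
        for i, p in enumerate(series):
            lo = max(0, i + 1 - window)
            expected = sum(a.delta("task") for a in acts[lo : i + 1]) / (i + 1 - lo)
            assert p.vergence == pytest.approx(expected)

    def test_cumulative_last_point_equals_whole_dialogue(self, random_dialogue):
        d = random_dialogue(11, p_delta_task=0.6)
        series = running_vergence(d, window="cumulative")
        assert series.points[-1].vergence == pytest.approx(vergence(d.acts(), "task"))

    def test_full_window_last_point_equals_whole_dialogue(self, random_dialogue):
        d = random_dialogue(12, p_delta_task=0.4)
        n = len(d.acts())
        series = running_vergence(d, window=n)
        assert series.points[-1].vergence == pytest.approx(vergence(d.acts(), "task"))

    def test_speaker_restriction(self, random_dialogue):
        d = random_dialogue(5)
        speaker = d.participants[0]
        series = running_vergence(d, window="cumulative", speaker=speaker)
        own = d.speaker_acts(speaker)
        assert series.points[-1].vergence == pytest.approx(vergence(own, "task"))
        assert len(series) == len(own)

    def test_strict_mode_rejects_oversized_window(self, monte_cristo):
        with pytest.raises(ValueError, match="window"):
            running_vergence(monte_cristo, window=100, strict=True)


class TestActTypeProfile:
    def test_proportions(self, make_acts):
        from twotk.core import build_dialogue

        acts = make_acts([(1, 0)] * 4)
        for a, t in zip(acts, [ActType.MK, ActType.MK, ActType.DO, ActType.DMK]):
            a.act_type = t
        d = build_dialogue(acts, participants=["A", "B"])
        prof = act_type_profile(d, "A")
        assert prof[ActType.MK] == 0.5
        assert prof[ActType.DO] == 0.25
        assert prof[ActType.DMK] == 0.25
        assert prof[ActType.DC] == prof[ActType.DM] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_and_complement_identity(self, random_dialogue, seed):
        d = random_dialogue(seed)
        for s in d.participants:
            if not d.speaker_acts(s):
                continue
            prof = act_type_profile(d, s)
            assert sum(prof.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
            # elaborative acts (DO + MK) complement the request-type acts
            do_mk = prof[ActType.DO] + prof[ActType.MK]
            rest = prof[ActType.DMK] + prof[ActType.DC] + prof[ActType.DM]
            assert do_mk == pytest.approx(1.0 - rest, abs=1e-9)

    def test_speaker_without_acts_is_undefined(self, make_acts):
        from twotk.core import build_dialogue

        d = build_dialogue(make_acts([(1, 0)]), participants=["A", "B"])
        with pytest.raises(UndefinedMetricError):
            act_type_profile(d, "B")


def _series(v, c):
    return MetricSeries(
        "per_concatenation", "task",
        [MetricPoint(i + 1, vi, ci, 1) for i, (vi, ci) in enumerate(zip(v, c))],
    )


class TestCorrelation:
    def test_perfectly_coupled_series(self):
        res = vc_correlation(_series([0.2, 0.5, 0.9], [0.2, 0.5, 0.9]))
        assert res.r == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        res = vc_correlation(_series([0.2, 0.4, 0.6, 0.8], [0.8, 0.6, 0.4, 0.2]))
        assert res.r == pytest.approx(-1.0)
        assert res.df == 2

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(42)
        v = rng.uniform(0, 1, 9)
        c = rng.uniform(0, 1, 9)
        res = vc_correlation(_series(v, c))
        # independent recomputation: covariance formula + t transform
        r = np.sum((v - v.mean()) * (c - c.mean())) / np.sqrt(
            np.sum((v - v.mean()) ** 2) * np.sum((c - c.mean()) ** 2)
        )
        t = r * np.sqrt(7 / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), df=7)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.df == 7

    def test_constant_series_is_degenerate(self):
        with pytest.raises(UndefinedMetricError):
            vc_correlation(_series([0.5, 0.5, 0.5], [0.1, 0.2, 0.3]))

    def test_too_few_points(self):
        with pytest.raises(UndefinedMetricError):
            vc_correlation(_series([0.1, 0.9], [0.2, 0.8]))


class TestPrimacy:
    def test_fixture_satisfies_primacy(self, monte_cristo):
        ok, bad = primacy_check(monte_cristo)
        assert ok and bad == []

    @pytest.mark.parametrize("seed", range(20))
    def test_validated_synthetic_always_passes(self, random_dialogue, seed):
        ok, _ = primacy_check(random_dialogue(seed))
        assert ok

    def test_invalid_acts_reported(self, make_acts):
        acts = make_acts([(0, 1), (1, 1)])  # first act decisive but not polarized
        ok, bad = primacy_check(acts)
        assert not ok
        assert bad == [1]
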