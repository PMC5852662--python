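import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streamdecode import behavior as bh


def _stream(presses, duration=30.0, **kw):
    return bh.ReportStream(
        presses=presses,
        condition=kw.get("condition", "neutral"),
        delta_f=kw.get("delta_f", 6.0),
        sequence_duration=duration,
    )


EXAMPLE = _stream(
    [(2.0, "integrated"), (10.0, "segregated"), (15.0, "integrated"),
     (22.0, "segregated")],
    duration=30.0,
)


class TestSegmentation:
    def test_worked_example(self):
        table = bh.segment_phases(EXAMPLE)
        assert [p.phase_class for p in table.phases] == [
            "initial_integrated", "segregated", "subsequent_integrated", "segregated",
        ]
        assert [p.duration for p in table.phases] == [8.0, 5.0, 7.0, 8.0]
        assert [p.completed for p in table.phases] == [True, True, True, False]

    def test_single_press_one_incomplete_phase(self):
        table = bh.segment_phases(_stream([(2.0, "integrated")], duration=150.0))
        assert len(table.phases) == 1
        assert table.phases[0].phase_class == "initial_integrated"
        assert not table.phases[0].completed
        assert table.phases[0].duration == 148.0

    def test_durations_conserve_reported_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            times = np.sort(rng.uniform(0, 100, size=n))
            times = times[np.concatenate([[True], np.diff(times) > 1e-6])]
            percepts = ["integrated" if i % 2 == 0 else "segregated"
                        for i in range(len(times))]
            reports = _stream(list(zip(times, percepts)), duration=100.0)
            table = bh.segment_phases(reports)
            assert sum(p.duration for p in table.phases) == pytest.approx(
                100.0 - times[0]
            )

    def test_non_alternating_stream_rejected(self):
        with pytest.raises(ValueError, match="alternate"):
            _stream([(1.0, "integrated"), (2.0, "integrated")])


class TestSequenceCriteria:
    def test_example_qualifies(self):
        assert bh.sequence_meets_criteria(bh.segment_phases(EXAMPLE))

    def test_first_phase_segregated_fails(self):
        table = bh.segment_phases(
            _stream([(2.0, "segregated"), (10.0, "integrated"), (15.0, "segregated"),
                     (20.0, "integrated")])
        )
        assert not bh.sequence_meets_criteria(table)

    def test_single_completed_subsequent_phase_fails(self):
        table = bh.segment_phases(
            _stream([(2.0, "integrated"), (10.0, "segregated"), (15.0, "integrated")])
        )
        assert not bh.sequence_meets_criteria(table)


class TestPercentSegregation:
    def test_worked_example(self):
        assert bh.percent_segregation(EXAMPLE) == pytest.approx(13 / 28 * 100)

    def test_always_segregated_is_100(self):
        assert bh.percent_segregation(
            _stream([(2.0, "segregated")], duration=30.0)
        ) == pytest.approx(100.0)

    def test_symmetric_stream_near_50(self):
        presses = [(float(t), "integrated" if i % 2 == 0 else "segregated")
                   for i, t in enumerate(range(0, 100, 5))]
        pct = bh.percent_segregation(_stream(presses, duration=100.0))
        assert pct == pytest.approx(50.0, abs=3.0)

    def test_no_presses_flagged(self):
        with pytest.raises(ValueError, match="press"):
            bh.percent_segregation(_stream([], duration=30.0))


class TestTransformedMeans:
    def test_logit_fixed_point(self):
        assert bh.transformed_condition_means(np.array([50.0]), "logit") == 50.0

    def test_log_mean_is_geometric(self):
        assert bh.transformed_condition_means(
            np.array([1.0, 100.0]), "log"
        ) == pytest.approx(10.0)

    def test_logit_symmetry(self):
        assert bh.transformed_condition_means(
            np.array([20.0, 80.0]), "logit"
        ) == pytest.approx(50.0)

    def test_strict_mode_rejects_boundaries(self):
        with pytest.raises(ValueError, match="strictly inside"):
            bh.transformed_condition_means(np.array([0.0, 50.0]), "logit")

    def test_lenient_mode_applies_empirical_correction(self):
        out = bh.transformed_condition_means(
            np.array([0.0, 100.0]), "logit", strict=False
        )
        assert 0.0 < out < 100.0


class TestRmAnova:
    def test_two_level_F_equals_t_squared(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(0.4, 0.5, size=12)
        wide = pd.DataFrame({"a": x, "b": y})
        aov = bh.rm_anova_hf(wide, n_boot=0)
        t = bh.paired_t_with_d(y, x)
        assert aov.F == pytest.approx(t.t**2, rel=1e-9)
        assert aov.epsilon_hf == 1.0

    def test_manual_F_matches_pingouin(self, rng):
        wide = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        aov = bh.rm_anova_hf(wide, n_boot=0)
        assert bh._rm_anova_F(wide.to_numpy()) == pytest.approx(aov.F, rel=1e-9)

    def test_null_p_values_uniform(self):
        """Under a true null the ANOVA p values are uniform (KS check)."""
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(300):
            wide = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
            F = bh._rm_anova_F(wide)
            ps.append(stats.f.sf(F, 2, 18))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_cells_rejected(self):
        wide = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, 3.0]})
        with pytest.raises(ValueError, match="complete"):
            bh.rm_anova_hf(wide)


class TestPairedT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        out = bh.paired_t_with_d(x, x)
        assert out.t == 0.0 and out.d == 0.0

    def test_constructed_effect_size(self):
        """25 differences with mean = 0.67 x their SD give d_z = 0.67."""
        rng = np.random.default_rng(1)
        diff = rng.normal(size=25)
        diff = (diff - diff.mean()) / diff.std(ddof=1)  # mean 0, sd 1
        diff = diff * 1.0 + 0.67
        out = bh.paired_t_with_d(diff)
        assert out.d == pytest.approx(0.67, abs=1e-9)
        assert out.t == pytest.approx(0.67 * np.sqrt(25), abs=1e-9)

    def test_hand_arithmetic_fixture(self):
        x = np.array([3.1, 2.7, 4.0, 3.3, 3.9])
        y = np.array([2.5, 2.9, 3.1, 2.8, 3.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        out = bh.paired_t_with_d(x, y)
        assert out.t == pytest.approx(t_hand, rel=1e-12)
        assert out.p == pytest.approx(p_hand, rel=1e-12)
        assert out.d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-12)

    def test_d_ci_inverts_noncentral_t(self):
        rng = np.random.default_rng(2)
        out = bh.paired_t_with_d(rng.normal(0.5, 1.0, size=20))
        lo, hi = out.d_ci
        assert lo < out.d < hi
        # the bounds are noncentrality values whose nct tail hits 2.5%
        assert stats.nct.cdf(out.t, 19, lo * np.sqrt(20)) == pytest.approx(0.975, abs=1e-6)
        assert stats.nct.cdf(out.t, 19, hi * np.sqrt(20)) == pytest.approx(0.025, abs=1e-6)

    def test_zero_variance_flagged(self):
        out = bh.paired_t_with_d(np.array([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 0.0]))
        assert np.isinf(out.t) and out.extra.get("zero_variance")


class TestWithinParticipantCI:
    def test_perfect_consistency_zero_width(self):
        base = np.array([[1.0], [2.0], [3.0]])
        wide = pd.DataFrame(np.hstack([base, base + 2.0]), columns=["a", "b"])
        out = bh.within_participant_ci(wide)
        assert np.allclose(out.ci_high - out.ci_low, 0.0, atol=1e-12)

    def test_two_condition_hand_computation(self):
        wide = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [2.0, 4.0, 5.0]})
        arr = wide.to_numpy()
        centered = arr - arr.mean(axis=1, keepdims=True) + arr.mean()
        corrected = (centered - centered.mean(0)) * np.sqrt(2.0) + centered.mean(0)
        sem = corrected.std(axis=0, ddof=1) / np.sqrt(3)
        half = stats.t.ppf(0.975, 2) * sem
        out = bh.within_participant_ci(wide)
        assert np.allclose(out.ci_high - out["mean"], half)

    def test_invariance_to_participant_offsets(self, rng):
        wide = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        shifted = wide.add(rng.normal(size=8) * 10.0, axis=0)
        a = bh.within_participant_ci(wide)
        b = bh.within_participant_ci(shifted)
        assert np.allclose(
            (a.ci_high - a.ci_low).to_numpy(), (b.ci_high - b.ci_low).to_numpy()
        )
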