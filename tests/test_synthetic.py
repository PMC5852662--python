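import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamdecode import synthetic_data as sd
from streamdecode import univariate as uv
from streamdecode.behavior import SEGREGATED, percent_segregation, segment_phases
from streamdecode.io import read_events


class TestStimulusTimeline:
    def test_250_triplets_last_150_seconds(self):
        tl = sd.build_stimulus_timeline(250)
        assert tl.duration == pytest.approx(150.0)

    def test_single_triplet_tone_onsets(self):
        tl = sd.build_stimulus_timeline(1)
        assert np.allclose(tl.tone_onsets[0], [0.0, 0.150, 0.300])
        assert tl.duration == pytest.approx(0.600)

    def test_semitone_formula(self):
        tl = sd.build_stimulus_timeline(10, h_freq=1017.0, delta_f=6.0)
        assert tl.tone_freqs[1] == pytest.approx(1017.0 * 2 ** (-0.5), abs=0.01)
        assert tl.tone_freqs[1] == pytest.approx(719.13, abs=0.01)

    @pytest.mark.parametrize(
        "kwargs", [{"n_triplets": 0}, {"n_triplets": 5, "h_freq": -1.0},
                   {"n_triplets": 5, "delta_f": 0.0}]
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            sd.build_stimulus_timeline(**kwargs)

    @given(n=st.integers(min_value=1, max_value=2000))
    @settings(max_examples=50, deadline=None)
    def test_duration_is_exactly_point_six_n(self, n):
        assert sd.build_stimulus_timeline(n).duration == pytest.approx(0.6 * n)


class TestFiller:
    def test_total_duration_rounds_to_40s(self, rng):
        table = sd.build_filler_timeline(rng)
        assert round(table.attrs["total_duration"]) == 40

    def test_tone_count_is_35(self, rng):
        table = sd.build_filler_timeline(rng)
        assert (table.event_type == "tone").sum() == 35

    def test_random_frequencies_in_bounds(self):
        rng = np.random.default_rng(5)
        freqs = []
        for _ in range(31):  # > 1000 random-frequency draws
            t = sd.build_filler_timeline(rng)
            freqs.extend(t.value.astype(float)[t.value.astype(float) != 250.0])
        freqs = np.asarray(freqs)
        assert len(freqs) >= 1000
        assert freqs.min() >= 200.0 and freqs.max() <= 2000.0


class TestPhaseSimulation:
    def test_degenerate_variance_gives_constant_durations(self, rng):
        params = sd.PerceptParams(
            mu_log_segregated=float(np.log(4.0)), sigma_log=0.0,
            between_participant_sd=0.0, delta_f_multiplier=1.0,
        )
        table, _ = sd.simulate_phase_sequence(params, "neutral", 6.0, 150.0, rng)
        seg = table.durations(SEGREGATED)
        assert len(seg) > 0
        assert np.allclose(seg, 4.0)

    def test_no_intention_effect_under_unit_multipliers(self):
        """With all multipliers 1 the percent-segregation distribution is
        identical across instruction conditions (two-sample KS check)."""
        from scipy.stats import ks_2samp

        null = sd.PerceptParams(
            intention_multipliers={c: 1.0 for c in
                                   ("neutral", "attempt_integration",
                                    "attend_high", "attend_low")},
        )
        rng = np.random.default_rng(11)
        samples = {}
        for cond in ("neutral", "attend_high"):
            samples[cond] = [
                percent_segregation(
                    sd.simulate_phase_sequence(null, cond, 6.0, 150.0, rng)[1]
                )
                for _ in range(150)
            ]
        assert ks_2samp(samples["neutral"], samples["attend_high"]).pvalue > 0.01

    def test_larger_delta_f_more_segregation(self, percept):
        rng = np.random.default_rng(12)
        pct = {
            df: np.mean(
                [
                    percent_segregation(
                        sd.simulate_phase_sequence(percept, "neutral", df, 150.0, rng)[1]
                    )
                    for _ in range(100)
                ]
            )
            for df in (4.0, 6.0)
        }
        assert pct[6.0] > pct[4.0]

    def test_phases_tile_reported_interval(self, percept, rng):
        for _ in range(50):
            table, reports = sd.simulate_phase_sequence(
                percept, "neutral", 6.0, 150.0, rng
            )
            total = sum(p.duration for p in table.phases)
            assert total == pytest.approx(150.0 - reports.presses[0][0])
            assert not table.phases[-1].completed

    def test_first_phase_integrated_and_presses_alternate(self, percept, rng):
        _, reports = sd.simulate_phase_sequence(percept, "neutral", 4.0, 150.0, rng)
        assert reports.presses[0][1] == "integrated"
        segment_phases(reports)  # raises on malformed streams


class TestSynthesizeRecording:
    def _setup(self, neural, n_triplets=20):
        tl = sd.build_stimulus_timeline(n_triplets)
        phases, reports = sd.simulate_phase_sequence(
            sd.PerceptParams(
                mu_log_integrated=float(np.log(3.0)),
                mu_log_segregated=float(np.log(3.0)),
                mu_log_initial_integrated=float(np.log(3.0)),
            ),
            "neutral",
            6.0,
            tl.duration,
            np.random.default_rng(0),
        )
        return tl, phases

    def test_null_construction_identical_averages(self, flat_template):
        neural = sd.NeuralParams(noise_sd=0.0, segregation_effect_amplitude=0.0)
        tl, phases = self._setup(neural)
        rec = sd.synthesize_recording(tl, phases, neural, flat_template,
                                      np.random.default_rng(1))
        epochs = rec.data.reshape(tl.n_triplets, -1)
        assert np.allclose(epochs - epochs[0], 0.0)

    def test_noise_free_difference_is_effect_times_window_shape(self, flat_template):
        neural = sd.NeuralParams(noise_sd=0.0, segregation_effect_amplitude=1.7)
        tl, phases = self._setup(neural)
        rec = sd.synthesize_recording(tl, phases, neural, flat_template,
                                      np.random.default_rng(1))
        epochs = rec.data.reshape(tl.n_triplets, -1)
        percepts = sd._governing_percepts(tl.triplet_onsets, phases)
        seg = epochs[percepts == SEGREGATED].mean(axis=0)
        integ = epochs[percepts == "integrated"].mean(axis=0)
        t = np.arange(epochs.shape[1]) / tl.sample_rate
        expected = sd.segregation_bump(t, neural, flat_template)
        assert np.allclose(seg - integ, expected, atol=1e-12)
        outside = (t < 0.216) | (t > 0.288)
        assert np.allclose((seg - integ)[outside], 0.0)

    def test_mismatched_durations_raise(self, neural, flat_template, rng):
        tl = sd.build_stimulus_timeline(10)
        long_phases, _ = sd.simulate_phase_sequence(
            sd.PerceptParams(), "neutral", 6.0, 60.0, rng
        )
        with pytest.raises(ValueError, match="beyond"):
            sd.synthesize_recording(tl, long_phases, neural, flat_template, rng)

    def test_calibrated_cohort_effect_size_in_reported_interval(self, neural):
        """Group window effect (averaged-variance d) falls in the reported
        95% CI [0.12, 0.52] in at least 80% of cohort simulations."""
        hits = 0
        runs = 50
        for run in range(runs):
            rng = np.random.default_rng(60_000 + run)
            mi, ms = sd.simulate_cohort_condition_means(23, 140, neural, rng)
            _, stats = uv.window_effect(ms, mi, 250.0)
            hits += 0.12 <= stats.d_av <= 0.52
        assert hits / runs >= 0.8


class TestCohortGeneration:
    def test_determinism_byte_identical_events(self, tmp_path, fast_percept, neural):
        paths = []
        for name in ("a", "b"):
            out = sd.generate_cohort(
                tmp_path / name, 2, percept=fast_percept, neural=neural,
                seed=9, n_blocks=1, n_triplets=20,
            )
            paths.append(sorted(out.glob("*/*_events.tsv")))
        for pa, pb in zip(*paths):
            assert pa.read_bytes() == pb.read_bytes()

    def test_refuses_existing_nonempty_dir(self, tmp_path, fast_percept, neural):
        out = tmp_path / "cohort"
        sd.generate_cohort(out, 1, percept=fast_percept, neural=neural,
                           seed=0, n_blocks=1, n_triplets=5)
        with pytest.raises(FileExistsError):
            sd.generate_cohort(out, 1, percept=fast_percept, neural=neural,
                               seed=0, n_blocks=1, n_triplets=5)

    def test_default_schedule_5000_epochs_and_condition_counts(
        self, tmp_path, fast_percept, neural
    ):
        out = sd.generate_cohort(
            tmp_path / "c", 1, percept=fast_percept, neural=neural,
            seed=3, n_blocks=4, n_triplets=250, synthesize=False,
        )
        events = sorted(out.glob("p00/*_events.tsv"))
        assert len(events) == 20  # 4 blocks x 5 sequences
        n_triplets = sum(
            (read_events(p).event_type == "tone").sum() // 3 for p in events
        )
        assert n_triplets == 5000
        # per-block instruction counts
        for b in range(4):
            conds = [
                read_events(p).condition.iloc[0]
                for p in events
                if f"_b{b:02d}_" in p.name
            ]
            assert sorted(conds) == sorted(
                ["neutral", "neutral", "attempt_integration", "attend_high",
                 "attend_low"]
            )

    def test_neutral_sequences_never_consecutive_and_delta_f_alternates(self, rng):
        for _ in range(20):
            blocks = sd._block_schedule(rng, 4)
            for block in blocks:
                conds = [c for c, _ in block]
                idx = [i for i, c in enumerate(conds) if c == "neutral"]
                assert idx[1] - idx[0] > 1
                dfs = [df for _, df in block]
                assert all(a != b for a, b in zip(dfs, dfs[1:]))
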