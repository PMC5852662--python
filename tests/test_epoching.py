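import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamdecode import epoching as ep
from streamdecode import synthetic_data as sd
from streamdecode.behavior import INTEGRATED, SEGREGATED, ReportStream
from streamdecode.io import ContinuousRecording


def _stream(press_times, first="integrated", duration=150.0, **kw):
    percepts = [first if i % 2 == 0 else
                ("segregated" if first == "integrated" else "integrated")
                for i in range(len(press_times))]
    return ReportStream(
        presses=list(zip(press_times, percepts)),
        condition=kw.get("condition", "neutral"),
        delta_f=kw.get("delta_f", 6.0),
        sequence_duration=duration,
    )


def _epochs(n, duration=None, fs=250.0):
    duration = duration if duration is not None else n * 0.6
    return ep.EpochSet(
        data=np.zeros((n, 150)), onsets=np.arange(n) * 0.6, sample_rate=fs
    )


def _random_stream(rng, duration=150.0):
    n = int(rng.integers(1, 25))
    times = np.sort(rng.uniform(0.0, duration - 1e-6, size=n))
    times = times[np.concatenate([[True], np.diff(times) > 1e-3])]
    return _stream(times, duration=duration)


class TestExtractEpochs:
    def test_250_triplets_give_250_by_150(self, rng):
        tl = sd.build_stimulus_timeline(250, sample_rate=250.0)
        rec = ContinuousRecording(rng.standard_normal(int(150 * 250)), 250.0)
        out = ep.extract_epochs(rec, tl)
        assert out.data.shape == (250, 150)

    def test_first_epoch_of_noise_free_recording_is_evoked_kernel(
        self, flat_template
    ):
        neural = sd.NeuralParams(noise_sd=0.0, segregation_effect_amplitude=0.0)
        tl = sd.build_stimulus_timeline(5)
        phases, _ = sd.simulate_phase_sequence(
            sd.PerceptParams(), "neutral", 6.0, tl.duration, np.random.default_rng(0)
        )
        rec = sd.synthesize_recording(
            tl, phases, neural, flat_template, np.random.default_rng(0)
        )
        out = ep.extract_epochs(rec, tl)
        t = np.arange(600) / 1000.0
        assert np.allclose(out.data[0], sd.evoked_kernel(t, neural, flat_template))

    def test_matches_brute_force_indexing(self, rng):
        tl = sd.build_stimulus_timeline(40, sample_rate=250.0)
        rec = ContinuousRecording(rng.standard_normal(40 * 150), 250.0)
        out = ep.extract_epochs(rec, tl)
        brute = np.array(
            [
                rec.data[int(round(o * 250)) : int(round(o * 250)) + 150]
                for o in tl.triplet_onsets
            ]
        )
        assert np.array_equal(out.data, brute)

    def test_onset_beyond_recording_end_named_in_error(self, rng):
        tl = sd.build_stimulus_timeline(10, sample_rate=250.0)
        rec = ContinuousRecording(rng.standard_normal(5 * 150), 250.0)
        with pytest.raises(ValueError, match="beyond"):
            ep.extract_epochs(rec, tl)


class TestExclusion:
    def test_boundary_only_case(self):
        epochs = _epochs(250)
        mask = ep.apply_exclusion(epochs, _stream([0.0], duration=150.0))
        onsets = epochs.onsets
        expected = (onsets >= 1.5) & (onsets + 0.6 <= 148.5)
        assert np.array_equal(mask, expected)

    def test_minimum_interval_across_press_is_3600_ms(self):
        """Across a report boundary, the closest retained epochs are 3.6 s
        apart onset-to-onset (1.5 s guard + 0.6 s epoch + 1.5 s guard)."""
        onsets = np.arange(0.0, 150.0, 0.001)  # dense virtual epoch grid
        epochs = ep.EpochSet(
            data=np.zeros((len(onsets), 1)), onsets=onsets, sample_rate=250.0
        )
        press = 75.0
        mask = ep.apply_exclusion(epochs, _stream([0.0, press], duration=150.0))
        before = onsets[mask & (onsets < press)]
        after = onsets[mask & (onsets >= press)]
        gap = after.min() - before.max()
        assert gap == pytest.approx(3.6, abs=0.002)

    def test_mask_equals_brute_force_inequalities(self):
        rng = np.random.default_rng(77)
        epochs = _epochs(250)
        for _ in range(100):
            reports = _random_stream(rng)
            mask = ep.apply_exclusion(epochs, reports)
            bounds = np.concatenate([[0.0], reports.press_times, [150.0]])
            for onset, ok in zip(epochs.onsets, mask):
                last = bounds[bounds <= onset].max()
                nxt = bounds[bounds > onset].min() if np.any(bounds > onset) else 150.0
                expected = onset >= last + 1.5 and onset + 0.6 <= nxt - 1.5
                assert ok == expected

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_retention_monotone_in_guard(self, seed):
        rng = np.random.default_rng(seed)
        epochs = _epochs(250)
        reports = _random_stream(rng)
        fractions = [
            ep.apply_exclusion(epochs, reports, guard=g).mean()
            for g in np.linspace(0.0, 3.0, 7)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_no_retained_epoch_overlaps_guard_window(self, percept, rng):
        epochs = _epochs(250)
        for _ in range(20):
            _, reports = sd.simulate_phase_sequence(percept, "neutral", 6.0, 150.0, rng)
            mask = ep.apply_exclusion(epochs, reports)
            for press in reports.press_times:
                bad = (epochs.onsets + 0.6 > press - 1.5) & (epochs.onsets < press + 1.5)
                assert not np.any(mask & bad)


class TestLabeling:
    def test_interval_membership(self):
        epochs = ep.EpochSet(
            data=np.zeros((1, 150)), onsets=np.array([15.0]), sample_rate=250.0
        )
        reports = ReportStream(
            presses=[(10.0, SEGREGATED), (20.0, INTEGRATED)],
            condition="neutral",
            delta_f=6.0,
            sequence_duration=150.0,
        )
        assert ep.label_epochs(epochs, reports)[0] == SEGREGATED

    def test_no_presses_all_integrated(self):
        epochs = _epochs(20)
        reports = _stream([], duration=12.0)
        assert np.all(ep.label_epochs(epochs, reports) == INTEGRATED)

    def test_matches_brute_force_latest_press_scan(self):
        rng = np.random.default_rng(31)
        epochs = _epochs(250)
        for _ in range(100):
            reports = _random_stream(rng)
            labels = ep.label_epochs(epochs, reports)
            for onset, label in zip(epochs.onsets, labels):
                prior = [(t, p) for t, p in reports.presses if t <= onset]
                expected = prior[-1][1] if prior else INTEGRATED
                assert label == expected

    def test_exclude_before_first_segregated_flag(self):
        epochs = _epochs(100, duration=60.0)
        reports = _stream([2.0, 30.0], duration=60.0)  # seg report at 30 s
        labels = ep.label_epochs(epochs, reports, exclude_before_first_segregated=True)
        assert np.all(labels[epochs.onsets < 30.0] == "")
        assert np.all(labels[epochs.onsets >= 30.0] == SEGREGATED)


class TestMinCellGate:
    def _epochs_with_cells(self, counts):
        """counts: {(delta_f, percept): n} retained neutral epochs."""
        labels, dfs = [], []
        for (df, percept), n in counts.items():
            labels += [percept] * n
            dfs += [df] * n
        n_tot = len(labels)
        return ep.EpochSet(
            data=np.zeros((n_tot, 150)),
            onsets=np.arange(n_tot) * 0.6,
            sample_rate=250.0,
            labels=np.array(labels, dtype=object),
            delta_f=np.array(dfs),
            condition=np.array(["neutral"] * n_tot, dtype=object),
        )

    def test_all_cells_above_threshold_included(self):
        es = self._epochs_with_cells(
            {(4.0, INTEGRATED): 60, (4.0, SEGREGATED): 70,
             (6.0, INTEGRATED): 80, (6.0, SEGREGATED): 90}
        )
        assert ep.min_cell_count_gate(es, threshold=55)

    def test_five_epoch_cell_excluded(self):
        es = self._epochs_with_cells(
            {(4.0, INTEGRATED): 200, (4.0, SEGREGATED): 5,
             (6.0, INTEGRATED): 200, (6.0, SEGREGATED): 200}
        )
        assert not ep.min_cell_count_gate(es, threshold=55)

    def test_zero_threshold_degenerate_gate(self):
        es = self._epochs_with_cells({(4.0, INTEGRATED): 1, (4.0, SEGREGATED): 1})
        assert ep.min_cell_count_gate(es, threshold=0)
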