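"""Segmentation, thinning, standardization and pattern assembly."""

import logging

import numpy as np
import pytest

import gaitrefine as gr
from gaitrefine.preprocess import Normalization


def make_recording(n=100, channels=2, t_end=10.0):
    rng = np.random.default_rng(1)
    return gr.ActivationCycle(
        values=rng.uniform(0, 1, (channels, n)),
        sample_times=np.linspace(0.0, t_end, n, endpoint=False),
        muscle_names=[f"m{i:02d}" for i in range(channels)],
        subject_id="S01",
    )


class TestSegmentation:
    def test_three_events_give_two_cycles(self):
        rec = make_recording()
        cycles = gr.segment_cycles(rec, [0.0, 5.0, 10.0])
        assert len(cycles) == 2
        assert [c.cycle_index for c in cycles] == [0, 1]

    def test_boundary_events_partition_all_samples(self):
        rec = make_recording(n=60)
        cycles = gr.segment_cycles(rec, [0.0, 2.0, 7.0, 10.0])
        assert sum(c.n_samples for c in cycles) == rec.n_samples

    def test_event_on_sample_starts_the_later_cycle(self):
        rec = make_recording(n=10, t_end=10.0)  # samples at 0,1,...,9 s
        cycles = gr.segment_cycles(rec, [0.0, 4.0, 10.0])
        assert cycles[0].n_samples == 4  # samples 0..3: 4.0 belongs to cycle 1
        assert cycles[1].sample_times[0] == 4.0

    def test_fewer_than_two_events_rejected(self):
        with pytest.raises(ValueError, match="2 event"):
            gr.segment_cycles(make_recording(), [1.0])


class TestResampling:
    def test_linear_ramp_thins_to_closed_form(self):
        ramp = gr.ActivationCycle(
            values=np.linspace(0, 1, 101)[None, :],
            sample_times=np.linspace(0, 1, 101),
            muscle_names=["m00"],
        )
        out = gr.resample_to_grid(ramp, 20)
        np.testing.assert_allclose(out.values[0], np.arange(20) / 19, atol=1e-12)

    def test_idempotent_on_target_grid(self):
        rec = make_recording(n=20, t_end=1.0)
        once = gr.resample_to_grid(rec, 20)
        twice = gr.resample_to_grid(once, 20)
        np.testing.assert_allclose(once.values, rec.values)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_constant_channel_stays_constant_and_endpoints_exact(self):
        cyc = gr.ActivationCycle(
            values=np.vstack([np.full(31, 0.4), np.linspace(0, 1, 31)]),
            sample_times=np.linspace(0, 3, 31),
            muscle_names=["a", "b"],
        )
        out = gr.resample_to_grid(cyc, 7)
        assert np.all(out.values[0] == 0.4)
        assert out.values[1, 0] == cyc.values[1, 0]
        assert out.values[1, -1] == cyc.values[1, -1]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            gr.resample_to_grid(make_recording(), 1)


def make_samples(n, rng, steps=6, channels=2, subject="S01"):
    return [
        gr.ModelSample(
            input_sequence=rng.normal(0, 2, (steps, channels)),
            target_sequence=rng.normal(1, 3, (steps, 1)),
            identity=(subject, i % 4, i),
        )
        for i in range(n)
    ]


class TestStandardize:
    def test_round_trip_and_zero_mean(self):
        rng = np.random.default_rng(0)
        samples = make_samples(8, rng)
        std, record = gr.standardize(samples)
        x = np.concatenate([s.input_sequence for s in std])
        np.testing.assert_allclose(x.mean(axis=0), 0.0, atol=1e-9)
        back = [record.inverse(s) for s in std]
        for orig, b in zip(samples, back):
            np.testing.assert_allclose(b.input_sequence, orig.input_sequence, atol=1e-9)
            np.testing.assert_allclose(b.target_sequence, orig.target_sequence, atol=1e-9)

    def test_zero_variance_channel_uses_unit_sd(self, caplog):
        rng = np.random.default_rng(0)
        samples = make_samples(4, rng)
        for s in samples:
            s.input_sequence[:, 1] = 0.7  # constant channel
        with caplog.at_level(logging.WARNING):
            std, record = gr.standardize(samples)
        assert record.input_sd[1] == 1.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_test_fold_statistics_never_enter_the_fit(self):
        rng = np.random.default_rng(0)
        train = make_samples(6, rng)
        _, clean_record = gr.standardize(train)
        poisoned = make_samples(6, rng, subject="S02")
        for s in poisoned:
            s.input_sequence[:] = 1e6  # sentinel values in the held-out fold
        transformed, record = gr.standardize(poisoned, stats_source=train)
        np.testing.assert_array_equal(record.input_mean, clean_record.input_mean)
        np.testing.assert_array_equal(record.input_sd, clean_record.input_sd)
        # and the sentinel is mapped with training statistics only
        expect = (1e6 - record.input_mean) / record.input_sd
        np.testing.assert_allclose(
            transformed[0].input_sequence,
            np.broadcast_to(expect, transformed[0].input_sequence.shape),
        )

    def test_empty_training_fold_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Normalization.fit([])


class TestPatterns:
    def test_attention_kind_fixed_by_name(self):
        assert gr.InputPattern("One-Quarter", "m00").attention_kind == "temporal"
        assert gr.InputPattern("One-Entire", "m00").attention_kind == "temporal"
        assert gr.InputPattern("All-Entire", "m00").attention_kind == "spatial"

    @pytest.mark.parametrize(
        "name,shape", [("One-Entire", (20, 1)), ("One-Quarter", (5, 1)), ("All-Entire", (20, 20))]
    )
    def test_input_shapes(self, small_pairs, name, shape):
        sample = gr.build_pattern(small_pairs[0], gr.InputPattern(name, "m03"))
        assert sample.input_sequence.shape == shape
        assert sample.target_sequence.shape == (shape[0], 1)

    def test_unknown_muscle_lists_available(self, small_pairs):
        with pytest.raises(KeyError, match="m00"):
            gr.build_pattern(small_pairs[0], gr.InputPattern("One-Entire", "nope"))

    def test_inputs_from_simulated_targets_from_measured(self):
        sim = gr.ActivationCycle(
            values=np.full((2, 8), 0.25), sample_times=np.arange(8.0),
            muscle_names=["a", "b"], subject_id="S01",
        )
        mea = gr.ActivationCycle(
            values=np.full((2, 8), 0.75), sample_times=np.arange(8.0),
            muscle_names=["a", "b"], subject_id="S01",
        )
        pair = gr.PairedCycle(simulated=sim, measured=mea)
        for name in ("One-Entire", "All-Entire"):
            s = gr.build_pattern(pair, gr.InputPattern(name, "a"))
            assert np.all(s.input_sequence == 0.25)
            assert np.all(s.target_sequence == 0.75)

    def test_quarter_selects_requested_quarter(self, small_pairs):
        pair = small_pairs[0]
        for q in range(4):
            s = gr.build_pattern(pair, gr.InputPattern("One-Quarter", "m00", quarter_index=q))
            expect = pair.simulated.values[0][5 * q : 5 * q + 5]
            np.testing.assert_array_equal(s.input_sequence[:, 0], expect)


class TestLoso:
    def test_one_fold_per_subject_partitioning_dataset(self, small_pairs):
        folds = gr.loso_splits(small_pairs)
        assert len(folds) == 3
        seen = []
        for f in folds:
            assert {p.identity[0] for p in f.test} == {f.subject_id}
            assert all(p.identity[0] != f.subject_id for p in f.train)
            seen.extend(id(p) for p in f.test)
        assert sorted(seen) == sorted(id(p) for p in small_pairs)

    @pytest.mark.parametrize("n_subjects,expected", [(8, 8), (10, 10)])
    def test_fold_count_matches_subject_count(self, n_subjects, expected):
        spec = gr.DistortionSpec()
        pairs = gr.generate_dataset(n_subjects, 1, 1, spec, seed=0, n_channels=2)
        assert len(gr.loso_splits(pairs)) == expected

    def test_single_subject_rejected(self):
        spec = gr.DistortionSpec()
        pairs = gr.generate_dataset(1, 2, 1, spec, seed=0, n_channels=2)
        with pytest.raises(ValueError, match="2 subjects"):
            gr.loso_splits(pairs)
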