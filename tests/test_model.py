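"""Network mechanics: gradients, determinism, attention normalization,
shapes and the refine contract."""

import numpy as np
import pytest

import gaitrefine as gr
from gaitrefine.model import (
    ModelConfig,
    _backward_sample,
    _forward_sample,
    _init_params,
)


def finite_difference(params, cfg, x, y, key, idx, eps=1e-5):
    p = {k: v.copy() for k, v in params.items()}
    p[key].flat[idx] += eps
    l1 = np.mean((_forward_sample(p, cfg, x, y, cfg.teacher_forcing)[0] - y[:, 0]) ** 2)
    p[key].flat[idx] -= 2 * eps
    l2 = np.mean((_forward_sample(p, cfg, x, y, cfg.teacher_forcing)[0] - y[:, 0]) ** 2)
    return (l1 - l2) / (2 * eps)


@pytest.mark.parametrize(
    "kind,score,values,head,skeys,tf,channels",
    [
        ("temporal", "general", "input", "context", "summary", False, 1),
        ("temporal", "dot", "input", "full", "summary", False, 1),
        ("temporal", "general", "state", "full", "summary", True, 1),
        ("spatial", "general", "input", "context", "summary", False, 4),
        ("spatial", "general", "input", "context", "per_step", False, 4),
        ("spatial", "dot", "state", "full", "summary", False, 4),
    ],
)
def test_backprop_matches_numerical_gradients(kind, score, values, head, skeys, tf, channels):
    """Analytic BPTT agrees with central differences in every wiring."""
    cfg = ModelConfig(
        input_channels=channels, sequence_length=6, hidden_units=8,
        attention_kind=kind, score=score, attention_values=values,
        output_head=head, spatial_keys=skeys, teacher_forcing=tf, seed=3,
    )
    rng = np.random.default_rng(11)
    params = _init_params(cfg)
    for k in params:  # randomise biases too so gradients are generic
        params[k] = params[k] + rng.normal(0, 0.1, params[k].shape)
    x = rng.normal(0, 1, (6, channels))
    y = rng.normal(0, 1, (6, 1))
    out, _, caches = _forward_sample(params, cfg, x, y, tf)
    grads = _backward_sample(params, cfg, x, y, out, caches, tf)
    for key in params:
        g = grads[key]
        for idx in rng.choice(g.size, size=min(5, g.size), replace=False):
            ng = finite_difference(params, cfg, x, y, key, idx)
            assert g.flat[idx] == pytest.approx(ng, rel=1e-3, abs=1e-7), key


class TestForwardContract:
    def test_attention_rows_sum_to_one_on_random_inputs(self):
        cfg = ModelConfig(input_channels=3, sequence_length=10, hidden_units=12,
                          attention_kind="spatial", epochs=1, seed=0)
        params = _init_params(cfg)
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.normal(0, 3, (10, 3))
            _, att, _ = _forward_sample(params, cfg, x, None, False)
            np.testing.assert_allclose(att.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(att >= 0)

    def test_output_is_20_by_1_for_entire_cycle_config(self, tiny_temporal_model):
        model, _ = tiny_temporal_model
        x = np.random.default_rng(0).normal(0, 1, (20, 1))
        out, amap = model.forward(x)
        assert out.shape == (20, 1)
        assert amap.weights.shape == (20, 20)

    def test_forward_deterministic(self, tiny_temporal_model):
        model, _ = tiny_temporal_model
        x = np.random.default_rng(1).normal(0, 1, (20, 1))
        a, _ = model.forward(x)
        b, _ = model.forward(x)
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_names_expected_shape(self, tiny_temporal_model):
        model, _ = tiny_temporal_model
        with pytest.raises(ValueError, match=r"\(20, 1\)"):
            model.forward(np.zeros((7, 1)))


class TestTraining:
    def small_task(self, n=6, steps=8, seed=0):
        """Learnable toy mapping: target is the input shifted by one step."""
        rng = np.random.default_rng(seed)
        samples = []
        for i in range(n):
            x = rng.normal(0, 1, (steps, 1))
            samples.append(
                gr.ModelSample(
                    input_sequence=x,
                    target_sequence=np.roll(x[:, 0], -1)[:, None],
                    identity=("S01", 0, i),
                )
            )
        return samples

    def test_loss_decreases_on_learnable_task_majority_of_seeds(self):
        wins = 0
        for seed in range(5):
            cfg = ModelConfig(input_channels=1, sequence_length=8, hidden_units=16,
                              epochs=30, seed=seed)
            m = gr.train(cfg, self.small_task(seed=seed))
            wins += m.history["train"][-1] < m.history["train"][0]
        assert wins >= 3

    def test_same_seed_reproduces_weights_and_losses(self):
        cfg = ModelConfig(input_channels=1, sequence_length=8, hidden_units=12,
                          epochs=10, seed=21)
        samples = self.small_task()
        a = gr.train(cfg, samples, samples[:2])
        b = gr.train(cfg, samples, samples[:2])
        assert a.weights_hash() == b.weights_hash()
        assert a.history == b.history

    def test_history_has_one_entry_per_epoch(self):
        cfg = ModelConfig(input_channels=1, sequence_length=8, hidden_units=8,
                          epochs=7, seed=0)
        m = gr.train(cfg, self.small_task(), self.small_task(n=2, seed=9))
        assert len(m.history["train"]) == 7
        assert len(m.history["val"]) == 7
        assert np.all(np.isfinite(m.history["val"]))

    def test_single_pair_overfits_below_005_standardized(self, small_pairs):
        """Memorisation oracle: capacity far exceeds the 20 target samples."""
        pat = gr.InputPattern("One-Entire", "m00")
        std, rec = gr.standardize([gr.build_pattern(small_pairs[0], pat)])
        cfg = ModelConfig(input_channels=1, sequence_length=20, hidden_units=64,
                          epochs=400, attention_values="state", output_head="full",
                          grad_clip=0.0, seed=2)
        m = gr.train(cfg, std, normalization=rec, pattern_name=pat.name)
        out, _ = m.forward(std[0].input_sequence)
        rmse = float(np.sqrt(np.mean((out[:, 0] - std[0].target_sequence[:, 0]) ** 2)))
        assert rmse < 0.05

    def test_empty_training_set_rejected(self):
        cfg = ModelConfig(input_channels=1, sequence_length=8, epochs=1)
        with pytest.raises(ValueError, match="empty"):
            gr.train(cfg, [])

    def test_batch_accumulation_runs(self):
        cfg = ModelConfig(input_channels=1, sequence_length=8, hidden_units=8,
                          epochs=3, batch_size=3, seed=0)
        m = gr.train(cfg, self.small_task())
        assert len(m.history["train"]) == 3


class TestRefine:
    def test_refined_cycle_is_20_samples_in_unit_interval(self, tiny_temporal_model, small_pairs):
        model, pat = tiny_temporal_model
        out = gr.refine(model, small_pairs[0], pat)
        assert out.n_samples == 20
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        assert out.muscle_names == ["m00"]

    def test_pattern_mismatch_rejected(self, tiny_temporal_model, small_pairs):
        model, _ = tiny_temporal_model
        with pytest.raises(ValueError, match="One-Entire"):
            gr.refine(model, small_pairs[0], gr.InputPattern("One-Quarter", "m00"))

    def test_identity_task_is_learned(self):
        """With no distortion, refinement should not hurt the baseline."""
        spec = gr.DistortionSpec(temporal_shift=0.0, noise_sd=0.0)
        pairs = gr.generate_dataset(3, 4, 1, spec, seed=2, n_channels=4,
                                    measurement_noise_sd=0.02)
        pat = gr.InputPattern("One-Entire", "m00")
        samples = [gr.build_pattern(p, pat) for p in pairs]
        std, rec = gr.standardize(samples)
        cfg = ModelConfig(input_channels=1, sequence_length=20, hidden_units=64,
                          epochs=200, seed=4)
        model = gr.train(cfg, std, normalization=rec, pattern_name=pat.name)
        worse = 0
        for p in pairs:
            refined = gr.refine(model, p, pat)
            e_ref = gr.rmse(p.measured.values[0], refined.values[0])
            e_base = gr.rmse(p.measured.values[0], p.simulated.values[0])
            worse += e_ref > e_base + 0.02
        assert worse <= len(pairs) // 4


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_temporal_model, tmp_path):
        model, _ = tiny_temporal_model
        path = tmp_path / "model.npz"
        model.save(path)
        back = gr.TrainedModel.load(path)
        assert back.config == model.config
        assert back.pattern_name == model.pattern_name
        assert back.weights_hash() == model.weights_hash()
        x = np.random.default_rng(2).normal(0, 1, (20, 1))
        np.testing.assert_array_equal(model.forward(x)[0], back.forward(x)[0])
        np.testing.assert_allclose(
            back.normalization.input_mean, model.normalization.input_mean
        )
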