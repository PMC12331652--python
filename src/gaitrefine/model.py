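"""Seq2Seq refinement network: LSTM encoder-decoder with attention, in numpy.

The network maps a simulated muscle-activation sequence (the simulator's
estimate for one gait cycle, standardized, 20 samples) to the measured
activation sequence of a target muscle.  Two attention variants expose the
two distortion families:

* **temporal** — keys are encoder states at each input *time step*; the
  attention map shows which part of the input cycle each output sample is
  read from (a constant off-diagonal indicates a pure delay);
* **spatial** — the encoder runs once per input *channel* (shared weights)
  and keys are per-channel summaries; the attention map shows which
  muscles inform each output sample (actuator-redundancy coupling).

Training follows the published recipe for this architecture family:
squared-error loss, Adam, batch size 1, with hidden size and epochs
configurable.  Everything is implemented here (forward, full
backpropagation through time, Adam) because the refinement network *is*
the method under study; gradients are verified against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cycles import ActivationCycle, PairedCycle
from .preprocess import InputPattern, ModelSample, Normalization, build_pattern

__all__ = ["ModelConfig", "AttentionMap", "TrainedModel", "train", "refine"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the study recipe: 20-step sequences, 700 hidden units
    per recurrent layer, batch size 1, 700 epochs, Adam.  ``score`` selects
    the multiplicative attention form (plain dot product or bilinear
    "general"); ``attention_values`` selects what the attention weights
    average — the raw input samples (default; forces the weights to point
    at the inputs actually used, which keeps the maps interpretable) or
    the encoder hidden states (the classic wiring, where a summary state
    can carry the whole sequence); ``spatial_keys`` selects whether
    spatial attention keys are per-channel summary states (default) or
    the per-channel state at the current step.
    """

    input_channels: int = 1
    sequence_length: int = 20
    hidden_units: int = 700
    output_length: int | None = None
    attention_kind: str = "temporal"
    score: str = "general"
    attention_values: str = "input"
    output_head: str = "context"
    spatial_keys: str = "summary"
    epochs: int = 700
    batch_size: int = 1
    learning_rate: float = 1e-3
    teacher_forcing: bool = False
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.attention_kind not in ("temporal", "spatial"):
            raise ValueError("attention_kind must be 'temporal' or 'spatial'")
        if self.score not in ("dot", "general"):
            raise ValueError("score must be 'dot' or 'general'")
        if self.attention_values not in ("input", "state"):
            raise ValueError("attention_values must be 'input' or 'state'")
        if self.output_head not in ("context", "full"):
            raise ValueError("output_head must be 'context' or 'full'")
        if self.spatial_keys not in ("summary", "per_step"):
            raise ValueError("spatial_keys must be 'summary' or 'per_step'")
        if self.attention_kind == "temporal" and self.input_channels != 1:
            raise ValueError("temporal attention expects a single input channel")

    @property
    def out_len(self) -> int:
        return self.sequence_length if self.output_length is None else self.output_length


@dataclass
class AttentionMap:
    """Row-normalized attention weights from one forward pass.

    ``weights`` is ``(output_steps, key_count)``; each row is a softmax
    over keys.  Keys are input time steps (temporal) or input channels
    (spatial); ``cycle_fractions`` locates each output step in the gait
    cycle.
    """

    weights: np.ndarray
    kind: str
    key_labels: list[str]
    cycle_fractions: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be (output_steps, keys)")
        if np.any(self.weights < -1e-12):
            raise ValueError("attention weights must be non-negative")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("attention rows must sum to 1 (+-1e-6)")


# ---------------------------------------------------------------------------
# parameter initialisation

def _init_params(cfg: ModelConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    h = cfg.hidden_units
    k = 1.0 / np.sqrt(h)
    ctx_dim = 1 if cfg.attention_values == "input" else h
    head_dim = ctx_dim if cfg.output_head == "context" else h + ctx_dim

    def u(*shape):
        return rng.uniform(-k, k, shape)

    params = {
        "enc_Wx": u(4 * h, 1),
        "enc_Wh": u(4 * h, h),
        "enc_b": np.zeros(4 * h),
        "dec_Wx": u(4 * h, 1),
        "dec_Wh": u(4 * h, h),
        "dec_b": np.zeros(4 * h),
        "out_W": u(head_dim),
        "out_b": np.zeros(1),
    }
    if cfg.attention_values == "input" and cfg.output_head == "context":
        # start near the pass-through solution: output = attended input sample
        params["out_W"] = np.ones(1)
    # forget-gate bias of 1 stabilises early training
    params["enc_b"][h : 2 * h] = 1.0
    params["dec_b"][h : 2 * h] = 1.0
    if cfg.score == "general":
        params["att_W"] = u(h, h)
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# LSTM over a batch of sequences (batch axis = channels for spatial attention)

def _lstm_forward(Wx, Wh, b, X):
    """X: (B, T, D) -> hidden states (B, T, H) plus backward cache."""
    B, T, _ = X.shape
    H = Wh.shape[1]
    ZX = X @ Wx.T + b
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    cache = {
        "i": np.empty((B, T, H)), "f": np.empty((B, T, H)),
        "g": np.empty((B, T, H)), "o": np.empty((B, T, H)),
        "tc": np.empty((B, T, H)),
        "h_prev": np.empty((B, T, H)), "c_prev": np.empty((B, T, H)),
        "X": X, "Wx": Wx, "Wh": Wh,
    }
    for t in range(T):
        cache["h_prev"][:, t] = h
        cache["c_prev"][:, t] = c
        z = ZX[:, t] + h @ Wh.T
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        Hs[:, t] = h
        cache["i"][:, t], cache["f"][:, t] = i, f
        cache["g"][:, t], cache["o"][:, t] = g, o
        cache["tc"][:, t] = tc
    return Hs, cache


def _lstm_backward(cache, dHs):
    """Backprop injected hidden-state grads dHs (B, T, H) through the LSTM."""
    X, Wx, Wh = cache["X"], cache["Wx"], cache["Wh"]
    B, T, D = X.shape
    H = Wh.shape[1]
    dZ = np.empty((B, T, 4 * H))
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f = cache["i"][:, t], cache["f"][:, t]
        g, o = cache["g"][:, t], cache["o"][:, t]
        tc = cache["tc"][:, t]
        dht = dHs[:, t] + dh
        do = dht * tc
        dc = dc + dht * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * cache["c_prev"][:, t]
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dZ[:, t] = dz
        dh = dz @ Wh
        dc = dc * f
    flatZ = dZ.reshape(-1, 4 * H)
    grads = {
        "Wx": flatZ.T @ X.reshape(-1, D),
        "Wh": flatZ.T @ cache["h_prev"].reshape(-1, H),
        "b": flatZ.sum(axis=0),
    }
    dX = dZ @ Wx
    return dX, grads


# ---------------------------------------------------------------------------
# full forward/backward for one sample

def _encode(params, cfg: ModelConfig, x: np.ndarray):
    """Run the encoder; returns (keys-or-key-source, enc cache).

    Temporal: x is (T, 1) -> Hs (T, H) used directly as keys.
    Spatial:  x is (T, C) -> per-channel pass with shared weights,
    Hs (C, T, H); keys are final states (summary) or per-step states.
    """
    if cfg.attention_kind == "temporal":
        X = x[None, :, :]  # (1, T, 1)
    else:
        X = x.T[:, :, None]  # (C, T, 1)
    Hs, cache = _lstm_forward(params["enc_Wx"], params["enc_Wh"], params["enc_b"], X)
    return Hs, cache


def _keys_at(cfg: ModelConfig, Hs: np.ndarray, t: int) -> np.ndarray:
    """Attention keys for decoder step t.  (K, H) matrix."""
    if cfg.attention_kind == "temporal":
        return Hs[0]  # (T_in, H)
    if cfg.spatial_keys == "summary":
        return Hs[:, -1, :]  # (C, H)
    ti = min(t, Hs.shape[1] - 1)
    return Hs[:, ti, :]  # (C, H)


def _forward_sample(params, cfg: ModelConfig, x: np.ndarray, target: np.ndarray | None,
                    teacher_forcing: bool = False):
    """Forward pass for one standardized sample.

    Returns (outputs (T_out,), attention (T_out, K), caches) — caches are
    retained for the backward pass.
    """
    H = cfg.hidden_units
    T_out = cfg.out_len
    scale = 1.0 / np.sqrt(H)  # temperature: keeps initial scores in softmax's sensitive range
    Hs, enc_cache = _encode(params, cfg, x)
    Wx, Wh, b = params["dec_Wx"], params["dec_Wh"], params["dec_b"]
    out_W, out_b = params["out_W"], params["out_b"]
    Wa = params.get("att_W")

    h = np.zeros(H)
    c = np.zeros(H)
    y_prev = 0.0
    outputs = np.empty(T_out)
    att = np.empty((T_out, _keys_at(cfg, Hs, 0).shape[0]))
    steps = []
    for t in range(T_out):
        x_in = target[t - 1, 0] if (teacher_forcing and t > 0) else y_prev
        z = Wx[:, 0] * x_in + Wh @ h + b
        i = _sigmoid(z[:H])
        f = _sigmoid(z[H : 2 * H])
        g = np.tanh(z[2 * H : 3 * H])
        o = _sigmoid(z[3 * H :])
        c_prev, h_prev = c, h
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        K = _keys_at(cfg, Hs, t)
        q = h if Wa is None else Wa @ h
        s = scale * (K @ q)
        s = s - s.max()
        e = np.exp(s)
        a = e / e.sum()
        if cfg.attention_values == "input":
            # value of key s/channel c is the raw input sample it indexes
            V = x if cfg.attention_kind == "temporal" else x[t][:, None]
        else:
            V = K
        ctx = a @ V
        if cfg.output_head == "context":
            y = float(out_W @ ctx + out_b[0])
        else:
            y = float(out_W[:H] @ h + out_W[H:] @ ctx + out_b[0])
        outputs[t] = y
        att[t] = a
        steps.append(
            dict(x_in=x_in, i=i, f=f, g=g, o=o, tc=tc, c_prev=c_prev, h_prev=h_prev,
                 h=h, a=a, q=q, ctx=ctx, K=K, V=V)
        )
        y_prev = y
    return outputs, att, (Hs, enc_cache, steps)


def _backward_sample(params, cfg: ModelConfig, x, target, outputs, caches,
                     teacher_forcing: bool):
    """Backprop d(mean squared error)/d(params) for one sample."""
    H = cfg.hidden_units
    T_out = cfg.out_len
    scale = 1.0 / np.sqrt(H)  # temperature: keeps initial scores in softmax's sensitive range
    Hs, enc_cache, steps = caches
    Wx, Wh = params["dec_Wx"], params["dec_Wh"]
    out_W = params["out_W"]
    Wa = params.get("att_W")

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dHs = np.zeros_like(Hs)
    dZ = np.empty((T_out, 4 * H))
    xin = np.empty((T_out, 1))
    hprev = np.empty((T_out, H))

    dy_from_next = 0.0
    dh_rec = np.zeros(H)
    dc_rec = np.zeros(H)
    resid = 2.0 * (outputs - target[:, 0]) / T_out
    for t in range(T_out - 1, -1, -1):
        st = steps[t]
        dy = resid[t] + dy_from_next
        # output head
        if cfg.output_head == "context":
            grads["out_W"] += dy * st["ctx"]
            grads["out_b"][0] += dy
            dh = dh_rec.copy()
            dctx = dy * out_W
        else:
            grads["out_W"][:H] += dy * st["h"]
            grads["out_W"][H:] += dy * st["ctx"]
            grads["out_b"][0] += dy
            dh = dy * out_W[:H] + dh_rec
            dctx = dy * out_W[H:]
        # attention: ctx = a @ V ; a = softmax(scale * K q)
        a, K, q, V = st["a"], st["K"], st["q"], st["V"]
        da = V @ dctx
        if cfg.attention_values == "state":
            dK = np.outer(a, dctx)
        else:
            dK = np.zeros_like(K)  # values are data; no grad path to the encoder
        ds = a * (da - a @ da)
        dq = scale * (K.T @ ds)
        dK += scale * np.outer(ds, q)
        if Wa is None:
            dh = dh + dq
        else:
            grads["att_W"] += np.outer(dq, st["h"])
            dh = dh + Wa.T @ dq
        # route key grads to encoder states
        if cfg.attention_kind == "temporal":
            dHs[0] += dK
        elif cfg.spatial_keys == "summary":
            dHs[:, -1, :] += dK
        else:
            dHs[:, min(t, Hs.shape[1] - 1), :] += dK
        # decoder LSTM cell
        i, f, g, o, tc = st["i"], st["f"], st["g"], st["o"], st["tc"]
        do = dh * tc
        dc = dc_rec + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * st["c_prev"]
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)]
        )
        dZ[t] = dz
        xin[t, 0] = st["x_in"]
        hprev[t] = st["h_prev"]
        dh_rec = Wh.T @ dz
        dc_rec = dc * f
        dx_in = float(Wx[:, 0] @ dz)
        dy_from_next = 0.0 if (teacher_forcing or t == 0) else dx_in
    grads["dec_Wx"] += dZ.T @ xin
    grads["dec_Wh"] += dZ.T @ hprev
    grads["dec_b"] += dZ.sum(axis=0)
    dX_enc, enc_grads = _lstm_backward(enc_cache, dHs)
    grads["enc_Wx"] += enc_grads["Wx"]
    grads["enc_Wh"] += enc_grads["Wh"]
    grads["enc_b"] += enc_grads["b"]
    return grads


def _clip_global(grads: dict[str, np.ndarray], max_norm: float) -> None:
    if max_norm <= 0:
        return
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        f = max_norm / total
        for g in grads.values():
            g *= f


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# public model object

@dataclass
class TrainedModel:
    """Weights + configuration + loss history of a trained refiner."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    history: dict[str, list[float]]
    normalization: Normalization | None = None
    pattern_name: str = ""
    input_labels: list[str] = field(default_factory=list)

    def forward(self, input_sequence: np.ndarray) -> tuple[np.ndarray, AttentionMap]:
        """Refine one standardized input sequence.

        Returns ``(refined (output_steps, 1), AttentionMap)``; deterministic
        given the stored weights.
        """
        x = np.atleast_2d(np.asarray(input_sequence, float))
        if (
            self.config.input_channels == 1
            and x.shape == (1, self.config.sequence_length)
            and self.config.sequence_length > 1
        ):
            x = x.T  # accept a bare 1-D sequence for single-channel models
        expected = (self.config.sequence_length, self.config.input_channels)
        if x.shape != expected:
            raise ValueError(f"input shape {x.shape} does not match expected {expected}")
        outputs, att, _ = _forward_sample(self.params, self.config, x, None, False)
        kind = self.config.attention_kind
        if kind == "temporal":
            labels = [str(i) for i in range(self.config.sequence_length)]
        elif len(self.input_labels) == self.config.input_channels:
            labels = list(self.input_labels)
        else:
            labels = [f"ch{i}" for i in range(self.config.input_channels)]
        t_out = self.config.out_len
        amap = AttentionMap(
            weights=att,
            kind=kind,
            key_labels=labels,
            cycle_fractions=np.arange(t_out) / max(t_out - 1, 1),
        )
        return outputs[:, None], amap

    def loss_on(self, samples: Sequence[ModelSample]) -> float:
        """Mean squared error over a standardized sample collection."""
        total = 0.0
        for s in samples:
            out, _, _ = _forward_sample(self.params, self.config, s.input_sequence, None, False)
            total += float(np.mean((out - s.target_sequence[:, 0]) ** 2))
        return total / len(samples)

    def weights_hash(self) -> str:
        import hashlib

        md = hashlib.sha256()
        for k in sorted(self.params):
            md.update(k.encode())
            md.update(np.ascontiguousarray(self.params[k]).tobytes())
        return md.hexdigest()

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + config + normalization + history."""
        meta = {
            "config": asdict(self.config),
            "history": self.history,
            "pattern_name": self.pattern_name,
            "input_labels": self.input_labels,
            "normalization": None if self.normalization is None else self.normalization.to_dict(),
        }
        np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {k: data[k] for k in data.files if k != "__meta__"}
        norm = meta["normalization"]
        return cls(
            params=params,
            config=ModelConfig(**meta["config"]),
            history=meta["history"],
            normalization=None if norm is None else Normalization.from_dict(norm),
            pattern_name=meta["pattern_name"],
            input_labels=meta.get("input_labels", []),
        )


def train(
    config: ModelConfig,
    train_samples: Sequence[ModelSample],
    val_samples: Sequence[ModelSample] = (),
    *,
    normalization: Normalization | None = None,
    pattern_name: str = "",
    input_labels: list[str] | None = None,
) -> TrainedModel:
    """Train the refiner on standardized samples.

    Stochastic-gradient training with Adam on the squared-error loss;
    samples are visited in a seeded random order each epoch and parameters
    updated every ``batch_size`` samples (default 1, the study recipe).
    Per-epoch training and validation losses are recorded.  Fully
    deterministic given ``config.seed``.
    """
    train_samples = list(train_samples)
    if not train_samples:
        raise ValueError("training set is empty")
    for s in train_samples:
        if s.input_sequence.shape != (config.sequence_length, config.input_channels):
            raise ValueError(
                f"sample shape {s.input_sequence.shape} does not match config "
                f"{(config.sequence_length, config.input_channels)}"
            )
    params = _init_params(config)
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history: dict[str, list[float]] = {"train": [], "val": []}
    if input_labels is None:
        input_labels = list(getattr(train_samples[0], "input_labels", []) or [])
    model = TrainedModel(params=params, config=config, history=history,
                         normalization=normalization, pattern_name=pattern_name,
                         input_labels=input_labels)
    n = len(train_samples)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        batch_grads = None
        in_batch = 0
        for j, idx in enumerate(order):
            s = train_samples[idx]
            outputs, _, caches = _forward_sample(
                params, config, s.input_sequence, s.target_sequence, config.teacher_forcing
            )
            epoch_loss += float(np.mean((outputs - s.target_sequence[:, 0]) ** 2))
            grads = _backward_sample(
                params, config, s.input_sequence, s.target_sequence, outputs, caches,
                config.teacher_forcing,
            )
            if batch_grads is None:
                batch_grads = grads
            else:
                for k in batch_grads:
                    batch_grads[k] += grads[k]
            in_batch += 1
            if in_batch == config.batch_size or j == n - 1:
                for k in batch_grads:
                    batch_grads[k] /= in_batch
                _clip_global(batch_grads, config.grad_clip)
                opt.step(params, batch_grads)
                batch_grads = None
                in_batch = 0
        history["train"].append(epoch_loss / n)
        history["val"].append(model.loss_on(val_samples) if val_samples else float("nan"))
    return model


def refine(
    model: TrainedModel, pair: PairedCycle, pattern: InputPattern
) -> ActivationCycle:
    """Refine one paired cycle's target muscle back into activation units.

    The pair is arranged per ``pattern``, standardized with the model's
    stored normalization record, passed through the network, then
    de-standardized and clipped to [0, 1].
    """
    if model.pattern_name and model.pattern_name != pattern.name:
        raise ValueError(
            f"model was trained for pattern {model.pattern_name!r}, not {pattern.name!r}"
        )
    if model.normalization is None:
        raise ValueError("model carries no normalization record; cannot de-standardize")
    sample = build_pattern(pair, pattern)
    x = model.normalization.transform_input(sample.input_sequence)
    out_std, _ = model.forward(x)
    refined = np.clip(model.normalization.inverse_target(out_std[:, 0]), 0.0, 1.0)
    n = pair.measured.n_samples
    if pattern.name == "One-Quarter":
        q = n // 4
        sl = slice(pattern.quarter_index * q, (pattern.quarter_index + 1) * q)
        times = pair.measured.sample_times[sl]
    else:
        times = pair.measured.sample_times
    return ActivationCycle(
        values=refined[None, :],
        sample_times=times,
        muscle_names=[pattern.target_muscle],
        subject_id=pair.identity[0],
        speed_id=pair.identity[1],
        cycle_index=pair.identity[2],
    )
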