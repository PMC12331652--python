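"""Analyses of trained attention maps.

Three diagnostics, mirroring how attention is read in this problem:

* **temporal offset** — where along the input cycle each output sample
  looks; a constant positive offset means the network reads "ahead" by
  that many samples, i.e. it has localised a pure delay;
* **top-k spatial ranking** — which muscles carry the most attention
  weight at chosen gait-cycle fractions (heel strike, mid-swing, next
  heel strike);
* **shortcut probe** — feeds frequency- and phase-perturbed cycles to a
  trained model; a model that learned the intended temporal correction
  (rather than an average waveform tied to movement duration) should
  degrade on such inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cycles import PairedCycle
from .model import AttentionMap, TrainedModel, refine
from .preprocess import InputPattern
from .stats import improvement_rate, rmse, t_test_vs_zero

__all__ = [
    "TemporalAttentionSummary",
    "SpatialRanking",
    "ProbeReport",
    "temporal_offset",
    "top_k_muscles",
    "shortcut_probe",
    "attention_to_frame",
    "ranking_to_frame",
    "ranking_to_markdown",
]


@dataclass
class TemporalAttentionSummary:
    """Where each output step's attention peaks, and the mean offset.

    Offsets are circular (the cycle is periodic) and signed: +k means the
    network reads the input k samples *later* in the cycle than the output
    sample it is producing.
    """

    argmax_steps: np.ndarray
    offsets: np.ndarray
    mean_offset: float
    mean_offset_fraction: float
    concentration: np.ndarray


def temporal_offset(amap: AttentionMap) -> TemporalAttentionSummary:
    """Mean circular offset between attention argmax and output step."""
    if amap.kind != "temporal":
        raise ValueError("temporal_offset requires a temporal attention map")
    w = amap.weights
    n_out, n_in = w.shape
    argmax = w.argmax(axis=1)
    raw = argmax - np.arange(n_out)
    offsets = (raw + n_in / 2) % n_in - n_in / 2  # wrap to (-n_in/2, n_in/2]
    mean = float(offsets.mean())
    return TemporalAttentionSummary(
        argmax_steps=argmax,
        offsets=offsets,
        mean_offset=mean,
        mean_offset_fraction=mean / n_in,
        concentration=w.max(axis=1),
    )


@dataclass
class SpatialRanking:
    """Top-k channels by attention weight at selected gait-cycle fractions."""

    k: int
    fractions: list[float]
    rankings: dict[float, list[tuple[str, float]]] = field(default_factory=dict)

    def labels_at(self, fraction: float) -> list[str]:
        return [name for name, _ in self.rankings[fraction]]


def top_k_muscles(
    amap: AttentionMap,
    k: int = 10,
    at_fractions: Sequence[float] = (0.0, 0.5, 1.0),
) -> SpatialRanking:
    """Rank channels by spatial attention at the decoder steps nearest the
    requested gait-cycle fractions.

    Ties are broken toward the lower channel index (stable sort), so the
    ranking is deterministic.
    """
    if amap.kind != "spatial":
        raise ValueError("top_k_muscles requires a spatial attention map")
    n_channels = amap.weights.shape[1]
    if k > n_channels:
        raise ValueError(f"k={k} exceeds the {n_channels} available channels")
    ranking = SpatialRanking(k=k, fractions=list(at_fractions))
    for f in at_fractions:
        step = int(np.argmin(np.abs(amap.cycle_fractions - f)))
        w = amap.weights[step]
        order = np.argsort(-w, kind="stable")[:k]
        ranking.rankings[f] = [(amap.key_labels[i], float(w[i])) for i in order]
    return ranking


def _warp_cycle(values: np.ndarray, freq: float, phase: float) -> np.ndarray:
    """Periodic frequency/phase warp of per-cycle channels.

    Reads the cycle at phases ``(freq * p + phase) mod 1`` — ``freq`` != 1
    stretches/compresses the waveform within its normalized window, and
    ``phase`` rotates it circularly.  Linear periodic interpolation; exact
    identity at freq 1, phase 0.
    """
    n = values.shape[1]
    p = np.arange(n) / n
    src = (freq * p + phase) % 1.0
    grid = np.concatenate([p, [1.0]])
    out = np.empty_like(values)
    for ch in range(values.shape[0]):
        ext = np.concatenate([values[ch], [values[ch, 0]]])
        out[ch] = np.interp(src, grid, ext)
    return out


@dataclass
class ProbeReport:
    """Outcome of the shortcut-learning probe."""

    er_values: np.ndarray
    mean_er: float
    t: float
    p: float
    freqs: np.ndarray
    phases: np.ndarray


def shortcut_probe(
    model: TrainedModel,
    base_pairs: Sequence[PairedCycle],
    pattern: InputPattern,
    n_variants: int = 32,
    seed: int = 0,
    *,
    freq_range: tuple[float, float] = (0.8, 1.25),
    phase_range: tuple[float, float] = (0.0, 1.0),
) -> ProbeReport:
    """Test a trained model on randomly frequency- and phase-changed cycles.

    Each variant warps one base cycle (input *and* target identically),
    refines it, and scores the improvement rate against the warped
    baseline.  H0: mean Er = 0 is tested with the one-sample t-test.
    A model specialised to the training timing should show mean Er > 0
    (degradation) under strong perturbation.
    """
    if not base_pairs:
        raise ValueError("base_pairs is empty")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, n_variants)
    phases = rng.uniform(*phase_range, n_variants)
    ers = np.empty(n_variants)
    ti = base_pairs[0].measured.channel_index(pattern.target_muscle)
    for v in range(n_variants):
        base = base_pairs[v % len(base_pairs)]
        sim = base.simulated.with_values(_warp_cycle(base.simulated.values, freqs[v], phases[v]))
        mea = base.measured.with_values(_warp_cycle(base.measured.values, freqs[v], phases[v]))
        pair = PairedCycle(simulated=sim, measured=mea)
        refined = refine(model, pair, pattern)
        target = mea.values[ti]
        baseline = sim.values[ti]
        if pattern.name == "One-Quarter":
            q = target.size // 4
            sl = slice(pattern.quarter_index * q, (pattern.quarter_index + 1) * q)
            target, baseline = target[sl], baseline[sl]
        e_pro = rmse(target, refined.values[0])
        e_sim = rmse(target, baseline)
        ers[v] = improvement_rate(e_pro, e_sim)
    t, p = t_test_vs_zero(ers)
    return ProbeReport(
        er_values=ers, mean_er=float(ers.mean()), t=t, p=p, freqs=freqs, phases=phases
    )


def attention_to_frame(amap: AttentionMap) -> pd.DataFrame:
    """Tabulate an attention map (rows = output steps, columns = keys)."""
    frame = pd.DataFrame(amap.weights, columns=amap.key_labels)
    frame.insert(0, "cycle_fraction", amap.cycle_fractions)
    return frame


def ranking_to_frame(ranking: SpatialRanking) -> pd.DataFrame:
    """Tabulate a top-k ranking: one row per (cycle fraction, rank)."""
    rows = [
        {"cycle_fraction": f, "rank": i + 1, "muscle": name, "weight": w}
        for f in ranking.fractions
        for i, (name, w) in enumerate(ranking.rankings[f])
    ]
    return pd.DataFrame(rows)


def ranking_to_markdown(ranking: SpatialRanking) -> str:
    """Render a top-k ranking as a Markdown table (one column per fraction)."""
    header = "| rank | " + " | ".join(f"{f:.0%}" for f in ranking.fractions) + " |"
    sep = "|---" * (len(ranking.fractions) + 1) + "|"
    lines = [header, sep]
    for i in range(ranking.k):
        cells = [
            f"{ranking.rankings[f][i][0]} ({ranking.rankings[f][i][1]:.3f})"
            for f in ranking.fractions
        ]
        lines.append(f"| {i + 1} | " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
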