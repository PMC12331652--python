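"""End-to-end experiment orchestration.

One call runs the full protocol for a dataset: arrange each paired cycle
into the requested input patterns, train one refiner per
leave-one-subject-out fold, score per-subject improvement rates, and
aggregate the statistics table (with Tukey comparisons across patterns
when all three are present).  All randomness flows from a single root
seed, so a config + seed pair reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .attention import attention_to_frame, temporal_offset, top_k_muscles
from .cycles import PairedCycle
from .io import cycle_to_frame, frame_to_cycle, read_table, write_sto
from .model import AttentionMap, ModelConfig, TrainedModel, refine, train
from .preprocess import Fold, InputPattern, build_pattern, loso_splits, standardize
from .stats import (
    ErSample,
    build_eval_table,
    rmse,
    subject_er,
    table_to_markdown,
    tukey_conditions,
)
from .synthetic import DistortionSpec, generate_dataset, near_identity_mixing

__all__ = [
    "ExperimentConfig",
    "PatternResult",
    "evaluate_pattern",
    "run_experiment",
    "save_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)


def _derive_seed(*parts: int) -> int:
    """Stable sub-seed below 2**31 derived from integer parts."""
    return int(np.random.default_rng(list(parts)).integers(2**31))


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    Synthetic-dataset parameters (used unless ``data_dir`` is given),
    the pattern/muscle grid, model overrides and the root seed.  Model
    defaults here are the desk-scale reduction (hidden 64, 100 epochs);
    the full-scale recipe (700/700) is a config away.
    """

    n_subjects: int = 6
    n_speeds: int = 4
    cycles_per_condition: int = 1
    n_channels: int = 20
    samples_per_cycle: int = 20
    measurement_noise_sd: float = 0.0
    temporal_shift: float = 0.075
    cycle_duration: float = 0.75
    peak_displacement: float = 0.0
    mixing_leakage: float = 0.0
    gain: float = 1.0
    noise_sd: float = 0.02
    data_dir: str | None = None
    patterns: tuple[str, ...] = ("One-Entire",)
    target_muscles: tuple[str, ...] = ("m00",)
    quarter_index: int = 0
    hidden_units: int = 64
    epochs: int = 100
    batch_size: int = 1
    learning_rate: float = 1e-3
    score: str = "general"
    spatial_keys: str = "summary"
    teacher_forcing: bool = False
    expected_speeds: int | None = 4
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("patterns", "target_muscles"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def distortion(self) -> DistortionSpec:
        mixing = (
            near_identity_mixing(self.n_channels, self.mixing_leakage)
            if self.mixing_leakage > 0
            else None
        )
        return DistortionSpec(
            temporal_shift=self.temporal_shift,
            cycle_duration=self.cycle_duration,
            peak_displacement=self.peak_displacement,
            mixing_matrix=mixing,
            gain=self.gain,
            noise_sd=self.noise_sd,
            seed=_derive_seed(self.seed, 7),
        )

    def make_pairs(self) -> list[PairedCycle]:
        if self.data_dir is not None:
            return load_dataset(self.data_dir)
        return generate_dataset(
            self.n_subjects,
            self.n_speeds,
            self.cycles_per_condition,
            self.distortion(),
            seed=self.seed,
            n_channels=self.n_channels,
            samples_per_cycle=self.samples_per_cycle,
            measurement_noise_sd=self.measurement_noise_sd,
        )


@dataclass
class FoldResult:
    """Trained model and per-cycle scores for one held-out subject."""

    subject_id: str
    model: TrainedModel
    er_sample: ErSample
    attention_maps: list[AttentionMap]
    per_cycle: pd.DataFrame


@dataclass
class PatternResult:
    """All folds of one (pattern, target muscle) experiment."""

    pattern: InputPattern
    folds: list[FoldResult]

    @property
    def er_samples(self) -> list[ErSample]:
        return [f.er_sample for f in self.folds]

    def mean_attention(self) -> AttentionMap:
        """Average attention weights over every held-out cycle of every fold."""
        maps = [m for f in self.folds for m in f.attention_maps]
        w = np.mean([m.weights for m in maps], axis=0)
        w = w / w.sum(axis=1, keepdims=True)
        first = maps[0]
        return AttentionMap(
            weights=w,
            kind=first.kind,
            key_labels=first.key_labels,
            cycle_fractions=first.cycle_fractions,
        )


def _model_config_for(pattern: InputPattern, cfg: ExperimentConfig, seed: int,
                      n_channels: int) -> ModelConfig:
    steps = pattern.steps(cfg.samples_per_cycle)
    return ModelConfig(
        input_channels=n_channels if pattern.name == "All-Entire" else 1,
        sequence_length=steps,
        hidden_units=cfg.hidden_units,
        attention_kind=pattern.attention_kind,
        score=cfg.score,
        spatial_keys=cfg.spatial_keys,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        teacher_forcing=cfg.teacher_forcing,
        seed=seed,
    )


def _score_fold(model: TrainedModel, fold: Fold, pattern: InputPattern,
                expected_speeds: int | None) -> tuple[ErSample, list[AttentionMap], pd.DataFrame]:
    """Refine every held-out cycle and aggregate per-speed RMSE into Er."""
    ti = fold.test[0].measured.channel_index(pattern.target_muscle)
    rows = []
    maps: list[AttentionMap] = []
    for pair in fold.test:
        refined = refine(model, pair, pattern)
        x_std = model.normalization.transform_input(build_pattern(pair, pattern).input_sequence)
        _, amap = model.forward(x_std)
        maps.append(amap)
        target = pair.measured.values[ti]
        baseline = pair.simulated.values[ti]
        if pattern.name == "One-Quarter":
            q = target.size // 4
            sl = slice(pattern.quarter_index * q, (pattern.quarter_index + 1) * q)
            target, baseline = target[sl], baseline[sl]
        rows.append(
            {
                "subject": pair.identity[0],
                "speed": pair.identity[1],
                "cycle": pair.identity[2],
                "e_refined": rmse(target, refined.values[0]),
                "e_baseline": rmse(target, baseline),
            }
        )
    per_cycle = pd.DataFrame(rows)
    by_speed = per_cycle.groupby("speed")[["e_refined", "e_baseline"]].mean()
    speed_errors = [tuple(r) for r in by_speed.to_numpy()]
    er = subject_er(
        speed_errors,
        subject_id=fold.subject_id,
        condition=pattern.name,
        muscle=pattern.target_muscle,
        expected_speeds=expected_speeds,
    )
    return er, maps, per_cycle


def evaluate_pattern(
    pairs: Sequence[PairedCycle],
    pattern: InputPattern,
    cfg: ExperimentConfig,
    pattern_index: int = 0,
) -> PatternResult:
    """Run the LOSO protocol for one pattern/target-muscle combination.

    Per fold: arrange samples, standardize with training-fold statistics,
    train a refiner (the held-out subject serves as the monitoring
    validation set only), then score every held-out cycle.
    """
    folds = loso_splits(pairs)
    results = []
    for fi, fold in enumerate(folds):
        try:
            train_samples = [build_pattern(p, pattern) for p in fold.train]
            test_samples = [build_pattern(p, pattern) for p in fold.test]
            train_std, record = standardize(train_samples)
            test_std = [record.transform(s) for s in test_samples]
            seed = _derive_seed(cfg.seed, 101, pattern_index, fi)
            mc = _model_config_for(pattern, cfg, seed, n_channels=pairs[0].simulated.n_channels)
            model = train(mc, train_std, test_std, normalization=record,
                          pattern_name=pattern.name)
            er, maps, per_cycle = _score_fold(model, fold, pattern, cfg.expected_speeds)
        except Exception as exc:
            raise RuntimeError(
                f"fold {fold.subject_id!r} failed ({pattern.name}/{pattern.target_muscle}): {exc}"
            ) from exc
        logger.info(
            "fold %s (%s/%s): Er = %+.3f", fold.subject_id, pattern.name,
            pattern.target_muscle, er.er,
        )
        results.append(
            FoldResult(
                subject_id=fold.subject_id,
                model=model,
                er_sample=er,
                attention_maps=maps,
                per_cycle=per_cycle,
            )
        )
    return PatternResult(pattern=pattern, folds=results)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    pattern_results: dict[tuple[str, str], PatternResult]
    eval_table: pd.DataFrame
    tukey: dict[str, pd.DataFrame]


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Full protocol: data -> patterns x muscles -> LOSO training -> table.

    When ``cfg.output_dir`` is set, writes the evaluation table (CSV and
    Markdown), Tukey comparisons, per-fold loss histories, mean attention
    maps and a manifest of seeds and weight hashes.
    """
    pairs = cfg.make_pairs()
    available = pairs[0].muscle_names
    for m in cfg.target_muscles:
        if m not in available:
            raise ValueError(f"target muscle {m!r} not in dataset ({', '.join(available)})")
    pattern_results: dict[tuple[str, str], PatternResult] = {}
    er_samples: list[ErSample] = []
    idx = 0
    for muscle in cfg.target_muscles:
        for pname in cfg.patterns:
            pattern = InputPattern(pname, muscle, quarter_index=cfg.quarter_index)
            try:
                res = evaluate_pattern(pairs, pattern, cfg, pattern_index=idx)
            except Exception as exc:
                raise RuntimeError(
                    f"experiment failed in pattern {pname!r}, muscle {muscle!r}: {exc}"
                ) from exc
            pattern_results[(pname, muscle)] = res
            er_samples.extend(res.er_samples)
            idx += 1
    eval_table = build_eval_table(er_samples)
    tukey: dict[str, pd.DataFrame] = {}
    if len(cfg.patterns) >= 2:
        for muscle in cfg.target_muscles:
            groups = {
                p: [s.er for s in pattern_results[(p, muscle)].er_samples]
                for p in cfg.patterns
            }
            tukey[muscle] = tukey_conditions(groups)
    result = ExperimentResult(
        config=cfg, pattern_results=pattern_results, eval_table=eval_table, tukey=tukey
    )
    if cfg.output_dir is not None:
        _write_artifacts(result, Path(cfg.output_dir))
    return result


def _write_artifacts(result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.eval_table.to_csv(outdir / "eval_table.csv", index=False, float_format="%.9g")
    (outdir / "eval_table.md").write_text(table_to_markdown(result.eval_table))
    for muscle, tk in result.tukey.items():
        tk.to_csv(outdir / f"tukey_{muscle}.csv", index=False, float_format="%.9g")
    from . import __version__

    manifest: dict = {
        "gaitrefine_version": __version__,
        "config": asdict(result.config),
        "folds": {},
    }
    for (pname, muscle), res in result.pattern_results.items():
        key = f"{pname}__{muscle}"
        amap = res.mean_attention()
        attention_to_frame(amap).to_csv(
            outdir / f"attention_{key}.csv", index=False, float_format="%.9g"
        )
        losses = pd.DataFrame(
            {
                f"{f.subject_id}_{split}": f.model.history[split]
                for f in res.folds
                for split in ("train", "val")
            }
        )
        losses.to_csv(outdir / f"loss_{key}.csv", index_label="epoch", float_format="%.9g")
        manifest["folds"][key] = {
            f.subject_id: {
                "er": f.er_sample.er,
                "model_seed": f.model.config.seed,
                "weights_sha256": f.model.weights_hash(),
            }
            for f in res.folds
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def save_dataset(pairs: Sequence[PairedCycle], directory: str | Path) -> None:
    """Write a paired dataset as .sto files, one per cycle and member."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for p in pairs:
        s, sp, cy = p.identity
        for member, cyc in (("sim", p.simulated), ("meas", p.measured)):
            write_sto(directory / f"{s}_speed{sp}_cycle{cy}_{member}.sto",
                      cycle_to_frame(cyc), name=f"{s} {member}")


def load_dataset(directory: str | Path) -> list[PairedCycle]:
    """Read a paired dataset written by :func:`save_dataset`."""
    directory = Path(directory)
    pairs = []
    for sim_path in sorted(directory.glob("*_sim.sto")):
        stem = sim_path.name[: -len("_sim.sto")]
        meas_path = directory / f"{stem}_meas.sto"
        if not meas_path.exists():
            raise FileNotFoundError(f"no measured counterpart for {sim_path.name}")
        subject, speed, cycle = stem.rsplit("_", 2)
        ident = dict(
            subject_id=subject,
            speed_id=int(speed.removeprefix("speed")),
            cycle_index=int(cycle.removeprefix("cycle")),
        )
        pairs.append(
            PairedCycle(
                simulated=frame_to_cycle(read_table(sim_path), **ident),
                measured=frame_to_cycle(read_table(meas_path), **ident),
            )
        )
    if not pairs:
        raise FileNotFoundError(f"no *_sim.sto files found in {directory}")
    return pairs
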