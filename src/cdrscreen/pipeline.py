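"""Convenience glue: normalize -> encode -> train -> evaluate in one call.

These helpers wire the modules together for experiments (and the example
scripts); each piece remains usable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cdrscreen.dataset import DatasetSplit, PairLabel
from cdrscreen.descriptors import DescriptorTable, normalize
from cdrscreen.evaluation import MetricReport, evaluate
from cdrscreen.model import TrainConfig, TrainedModel, build_network, predict, train
from cdrscreen.screening import encode_pairs
from cdrscreen.synthetic_data import SyntheticWorld


@dataclass
class ExperimentResult:
    trained: TrainedModel
    report: MetricReport
    split: DatasetSplit


def normalize_world(world: SyntheticWorld) -> tuple[DescriptorTable, DescriptorTable]:
    """Min-max normalize both tables (fitting on the whole synthetic set)."""
    return normalize(world.compounds), normalize(world.diseases)


def images_and_labels(
    pairs: Sequence[PairLabel],
    compounds: DescriptorTable,
    diseases: DescriptorTable,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode labeled pairs into a [0, 1] image stack and a 0/1 label array."""
    keys = [(p.compound_id, p.disease_id) for p in pairs]
    images = encode_pairs(keys, compounds, diseases)
    labels = np.array([1 if p.label == "positive" else 0 for p in pairs])
    return images, labels


def holdout_auc(
    world: SyntheticWorld,
    sample_size: int = 2000,
    epochs: int = 12,
    split_seed: int = 3,
    train_seed: int = 5,
) -> float:
    """Held-out AUC of a tiny CNN on a balanced random split of the world."""
    from cdrscreen.dataset import SplitSpec, complement_pool, make_ratio_datasets

    pos = world.positive_pairs
    pool = complement_pool(world.compounds.ids, world.diseases.ids, pos)
    spec = SplitSpec(
        ratio_neg_per_pos=1, sample_size=sample_size, repeats=1, seed=split_seed
    )
    split = make_ratio_datasets(pos, pool, spec)[0]
    result = run_experiment(
        world, split, TrainConfig.desk_scale(seed=train_seed, max_epochs=epochs)
    )
    return result.report.auc


def ratio_series(
    world: SyntheticWorld,
    ratios: Sequence[int] = (1, 2, 3, 4, 5),
    sample_size: int = 2400,
    repeats: int = 3,
    epochs: int = 12,
    split_seed: int = 11,
    train_seed: int = 5,
) -> dict[int, dict[str, float]]:
    """Mean test metrics per positive:negative ratio, averaged over repeats.

    Mirrors the benchmark's imbalance experiment: for each ratio the same
    world is resampled, split 75/25, and a fresh tiny CNN is trained; the
    reported numbers are repeat-averaged test-set metrics.
    """
    from cdrscreen.dataset import SplitSpec, complement_pool, make_ratio_datasets

    pos = world.positive_pairs
    pool = complement_pool(world.compounds.ids, world.diseases.ids, pos)
    out: dict[int, dict[str, float]] = {}
    for ratio in ratios:
        spec = SplitSpec(
            ratio_neg_per_pos=ratio, sample_size=sample_size,
            repeats=repeats, seed=split_seed,
        )
        splits = make_ratio_datasets(pos, pool, spec, ratios=(ratio,))
        reports = []
        for i, split in enumerate(splits):
            result = run_experiment(
                world, split,
                TrainConfig.desk_scale(seed=train_seed + i, max_epochs=epochs),
            )
            reports.append(result.report.as_dict())
        out[ratio] = {
            key: float(np.mean([r[key] for r in reports])) for key in reports[0]
        }
    return out


def run_experiment(
    world: SyntheticWorld,
    split: DatasetSplit,
    config: TrainConfig | None = None,
) -> ExperimentResult:
    """Train on the split's training pairs, report metrics on its test pairs."""
    compounds, diseases = normalize_world(world)
    x_train, y_train = images_and_labels(split.train, compounds, diseases)
    x_test, y_test = images_and_labels(split.test, compounds, diseases)
    if config is None:
        config = TrainConfig.desk_scale()
    model = build_network(
        config.architecture,
        input_shape=x_train.shape[1:],
        seed=config.seed,
    )
    trained = train(model, x_train, y_train, config)
    preds = predict(
        trained,
        x_test,
        compound_ids=[p.compound_id for p in split.test],
        disease_ids=[p.disease_id for p in split.test],
    )
    report = evaluate(preds, y_test)
    return ExperimentResult(trained=trained, report=report, split=split)
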