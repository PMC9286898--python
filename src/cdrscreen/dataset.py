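"""Benchmark assembly: negative sampling, ratio series, and held-out splits.

Positive compound-disease relationships come from curated databases; there is
no curated negative class, so negatives are sampled uniformly from the
complement of the positive set over the full compound x disease grid (the
reference benchmark drew 13,981 negatives from a pool of 176,819 unlabeled
pairs).  Three split modes are provided:

``random``
    draw a fixed-size sample at a chosen positive:negative ratio and split it
    75/25 preserving the ratio;
``disease_held_out``
    grow the training set disease-by-disease (every pair of a chosen disease
    goes to training) until a positive-count target is crossed, then draw the
    test set from the untouched diseases — no disease id appears on both
    sides;
``compound_held_out``
    the same procedure keyed on compound ids.

All draws are reproducible from an integer seed; per-repeat seeds are derived
as ``seed + repeat_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Label = Literal["positive", "negative", "unknown"]


@dataclass(frozen=True, order=True)
class PairLabel:
    compound_id: str
    disease_id: str
    label: Label = "unknown"
    evidence: str | None = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_id, self.disease_id)


@dataclass(frozen=True)
class SplitSpec:
    mode: Literal["random", "disease_held_out", "compound_held_out"] = "random"
    train_fraction: float = 0.75
    ratio_neg_per_pos: int = 1
    sample_size: int = 20000
    repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.ratio_neg_per_pos < 1:
            raise ValueError("ratio_neg_per_pos must be >= 1")


@dataclass
class DatasetSplit:
    train: list[PairLabel]
    test: list[PairLabel]
    provenance: dict

    def __post_init__(self) -> None:
        train_keys = {p.key for p in self.train}
        test_keys = {p.key for p in self.test}
        if len(train_keys) != len(self.train) or len(test_keys) != len(self.test):
            raise ValueError("duplicate pairs within a partition")
        overlap = train_keys & test_keys
        if overlap:
            raise ValueError(f"train and test share {len(overlap)} pairs")


def _check_ids(
    pairs: Iterable[PairLabel],
    compound_ids: Sequence[str],
    disease_ids: Sequence[str],
) -> None:
    compounds, diseases = set(compound_ids), set(disease_ids)
    for p in pairs:
        if p.compound_id not in compounds:
            raise ValueError(f"pair references unknown compound id {p.compound_id!r}")
        if p.disease_id not in diseases:
            raise ValueError(f"pair references unknown disease id {p.disease_id!r}")


def complement_pool(
    compound_ids: Sequence[str],
    disease_ids: Sequence[str],
    positives: Iterable[PairLabel],
) -> list[tuple[str, str]]:
    """All grid pairs not labeled positive, in deterministic (sorted) order.

    The result has exactly ``len(compounds) * len(diseases) - len(positives)``
    entries; together with the positives it tiles the full grid.
    """
    positives = list(positives)
    _check_ids(positives, compound_ids, disease_ids)
    known = {p.key for p in positives}
    if len(known) != len(positives):
        raise ValueError("duplicate positive pairs")
    pool = [
        (c, d)
        for c in sorted(compound_ids)
        for d in sorted(disease_ids)
        if (c, d) not in known
    ]
    return pool


def sample_negatives(
    pool: Sequence[tuple[str, str]], n: int, seed: int
) -> list[PairLabel]:
    """Uniform sample of ``n`` pool pairs without replacement, labeled negative."""
    if n > len(pool):
        raise ValueError(f"requested {n} negatives from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [PairLabel(pool[i][0], pool[i][1], "negative") for i in idx]


def _ratio_counts(sample_size: int, ratio: int) -> tuple[int, int]:
    n_pos = sample_size // (1 + ratio)
    return n_pos, sample_size - n_pos


def make_ratio_datasets(
    positives: Sequence[PairLabel],
    pool: Sequence[tuple[str, str]],
    spec: SplitSpec,
    ratios: Sequence[int] | None = None,
) -> list[DatasetSplit]:
    """Random-mode benchmark datasets at one or more positive:negative ratios.

    For each ratio ``r`` and each repeat, ``sample_size`` pairs are drawn with
    ``floor(sample_size / (1 + r))`` positives and the remainder negatives,
    then split 75/25 (``train_fraction``) with the class ratio preserved in
    both partitions.  Repeat ``k`` uses seed ``spec.seed + k``.
    """
    if ratios is None:
        ratios = (spec.ratio_neg_per_pos,)
    splits: list[DatasetSplit] = []
    for ratio in ratios:
        n_pos, n_neg = _ratio_counts(spec.sample_size, ratio)
        if n_pos > len(positives):
            raise ValueError(
                f"ratio 1:{ratio} at size {spec.sample_size} needs {n_pos} "
                f"positives but only {len(positives)} are available"
            )
        if n_neg > len(pool):
            raise ValueError(
                f"ratio 1:{ratio} at size {spec.sample_size} needs {n_neg} "
                f"negatives but the pool has {len(pool)}"
            )
        for repeat in range(spec.repeats):
            rng = np.random.default_rng(spec.seed + repeat)
            pos_idx = rng.choice(len(positives), size=n_pos, replace=False)
            pos = [
                PairLabel(positives[i].compound_id, positives[i].disease_id,
                          "positive", positives[i].evidence)
                for i in pos_idx
            ]
            neg = sample_negatives(pool, n_neg, seed=int(rng.integers(2**31)))
            n_pos_train = int(np.floor(spec.train_fraction * n_pos))
            n_neg_train = int(np.floor(spec.train_fraction * n_neg))
            pos_perm = rng.permutation(n_pos)
            neg_perm = rng.permutation(n_neg)
            train = [pos[i] for i in pos_perm[:n_pos_train]] + [
                neg[i] for i in neg_perm[:n_neg_train]
            ]
            test = [pos[i] for i in pos_perm[n_pos_train:]] + [
                neg[i] for i in neg_perm[n_neg_train:]
            ]
            splits.append(
                DatasetSplit(
                    train=train,
                    test=test,
                    provenance={
                        "mode": "random",
                        "ratio": ratio,
                        "repeat": repeat,
                        "seed": spec.seed + repeat,
                        "n_train_pos": n_pos_train,
                        "n_train_neg": n_neg_train,
                        "n_test_pos": n_pos - n_pos_train,
                        "n_test_neg": n_neg - n_neg_train,
                    },
                )
            )
    return splits


def _grouped_held_out(
    pairs: Sequence[PairLabel],
    key: str,
    n_train: int,
    n_test: int,
    rng: np.random.Generator,
) -> tuple[list[PairLabel], list[PairLabel], list[str]]:
    """Assign whole id-groups to train until ``n_train`` pairs are reached,
    then sample ``n_test`` pairs from the untouched groups."""
    groups: dict[str, list[PairLabel]] = {}
    for p in pairs:
        groups.setdefault(getattr(p, key), []).append(p)
    if len(groups) < 2:
        raise ValueError(
            f"held-out split needs >= 2 distinct {key}s, got {len(groups)}"
        )
    order = sorted(groups)
    rng.shuffle(order)
    train: list[PairLabel] = []
    used: list[str] = []
    i = 0
    while len(train) < n_train:
        if i >= len(order):
            raise ValueError(
                f"cannot reach {n_train} training pairs: only {len(train)} "
                f"available across all {key}s"
            )
        gid = order[i]
        train.extend(groups[gid])
        used.append(gid)
        i += 1
    remaining = [p for gid in order[i:] for p in groups[gid]]
    if len(remaining) < n_test:
        raise ValueError(
            f"only {len(remaining)} pairs remain outside the training "
            f"{key}s; cannot draw a test set of {n_test}"
        )
    test_idx = rng.choice(len(remaining), size=n_test, replace=False)
    test = [remaining[j] for j in test_idx]
    return train, test, used


def _held_out_split(
    positives: Sequence[PairLabel],
    negatives: Sequence[PairLabel],
    n_train_pos: int,
    n_test_pos: int,
    seed: int,
    key: str,
) -> DatasetSplit:
    rng = np.random.default_rng(seed)
    pos_train, pos_test, pos_groups = _grouped_held_out(
        positives, key, n_train_pos, n_test_pos, rng
    )
    neg_train, neg_test, neg_groups = _grouped_held_out(
        negatives, key, n_train_pos, n_test_pos, rng
    )
    test_groups_pos = {getattr(p, key) for p in pos_test}
    test_groups_neg = {getattr(p, key) for p in neg_test}
    cross_overlap = (set(pos_groups) & test_groups_neg) | (
        set(neg_groups) & test_groups_pos
    )
    return DatasetSplit(
        train=pos_train + neg_train,
        test=pos_test + neg_test,
        provenance={
            "mode": f"{key.removesuffix('_id')}_held_out",
            "seed": seed,
            "n_train_pos": len(pos_train),
            "n_train_neg": len(neg_train),
            "n_test_pos": len(pos_test),
            "n_test_neg": len(neg_test),
            "train_groups_pos": sorted(pos_groups),
            "train_groups_neg": sorted(neg_groups),
            "cross_class_group_overlap": sorted(cross_overlap),
        },
    )


def disease_held_out_split(
    positives: Sequence[PairLabel],
    negatives: Sequence[PairLabel],
    n_train_pos: int,
    n_test_pos: int,
    seed: int,
) -> DatasetSplit:
    """Split guaranteeing that no test disease occurs in training.

    Diseases are drawn in random order and all of a drawn disease's pairs go
    to the training set; the loop stops at the first crossing of
    ``n_train_pos`` (the overshoot is kept — truncating mid-disease would
    break the guarantee) and ``n_test_pos`` pairs are then sampled from the
    unassigned diseases.  The procedure runs independently for the positive
    and the negative class; realized counts and any cross-class disease
    overlap are recorded in the provenance.
    """
    return _held_out_split(
        positives, negatives, n_train_pos, n_test_pos, seed, key="disease_id"
    )


def compound_held_out_split(
    positives: Sequence[PairLabel],
    negatives: Sequence[PairLabel],
    n_train_pos: int,
    n_test_pos: int,
    seed: int,
) -> DatasetSplit:
    """Split guaranteeing that no test compound occurs in training."""
    return _held_out_split(
        positives, negatives, n_train_pos, n_test_pos, seed, key="compound_id"
    )


# ---------------------------------------------------------------------------
# I/O


def read_pairs(path: str | Path, delimiter: str = ",") -> list[PairLabel]:
    frame = pd.read_csv(path, sep=delimiter, dtype=str).fillna("")
    required = {"compound_id", "disease_id", "label"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: pairs file needs columns {sorted(required)}")
    pairs = [
        PairLabel(
            row.compound_id,
            row.disease_id,
            row.label,
            getattr(row, "evidence", "") or None,
        )
        for row in frame.itertuples()
    ]
    if len({p.key for p in pairs}) != len(pairs):
        raise ValueError(f"{path}: duplicate (compound_id, disease_id) pairs")
    return pairs


def write_pairs(pairs: Iterable[PairLabel], path: str | Path, delimiter: str = ",") -> None:
    frame = pd.DataFrame(
        [(p.compound_id, p.disease_id, p.label, p.evidence or "") for p in pairs],
        columns=["compound_id", "disease_id", "label", "evidence"],
    )
    frame.to_csv(path, sep=delimiter, index=False)


def write_split_manifest(split: DatasetSplit, path: str | Path) -> None:
    """Id-only JSON manifest of a split, for provenance."""
    payload = {
        "provenance": split.provenance,
        "train": [[p.compound_id, p.disease_id, p.label] for p in split.train],
        "test": [[p.compound_id, p.disease_id, p.label] for p in split.test],
    }
    Path(path).write_text(json.dumps(payload))


def read_split_manifest(path: str | Path) -> DatasetSplit:
    payload = json.loads(Path(path).read_text())
    return DatasetSplit(
        train=[PairLabel(c, d, lab) for c, d, lab in payload["train"]],
        test=[PairLabel(c, d, lab) for c, d, lab in payload["test"]],
        provenance=payload["provenance"],
    )
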