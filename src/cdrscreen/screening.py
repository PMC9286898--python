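"""Library screening: filter, enumerate, predict, rank.

A compound library is first reduced to pharmacologically plausible entries —
a compound is kept if it is a quality-control (QC) marker compound, is
detectable in blood, or has oral bioavailability strictly above a threshold
(default 30%).  Kept compounds are paired with every disease on the panel,
pairs already labeled in the benchmark are dropped, and the trained
classifier scores the remainder.  Results are ranked by descending
probability; two counts are reported: pairs predicted positive at the
model's 0.5 threshold, and high-confidence candidates above the stricter
candidate cut (default 0.9).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cdrscreen.dataset import PairLabel
from cdrscreen.descriptors import CompoundRecord, DescriptorTable
from cdrscreen.encoding import build_matrix, to_grayscale
from cdrscreen.model import TrainedModel, predict


@dataclass(frozen=True)
class ScreenConfig:
    ob_threshold: float = 30.0
    candidate_cut: float = 0.9
    combine: str = "or"  # "or": union of admissible classes; "and": all three

    def __post_init__(self) -> None:
        if self.ob_threshold < 0:
            raise ValueError("ob_threshold must be >= 0")
        if not 0.0 < self.candidate_cut < 1.0:
            raise ValueError("candidate_cut must lie in (0, 1)")
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")


@dataclass
class ScreenResult:
    """Ranked predictions plus summary counts."""

    entries: pd.DataFrame  # columns: compound_id, disease_id, probability, candidate
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.entries["probability"].to_numpy()
        if np.any(np.diff(p) > 0):
            raise ValueError("entries must be sorted by descending probability")


def _passes(record: CompoundRecord, config: ScreenConfig) -> bool:
    ob_ok = record.ob_percent is not None and record.ob_percent > config.ob_threshold
    clauses = (record.is_qc, record.is_blood, ob_ok)
    return any(clauses) if config.combine == "or" else all(clauses)


def filter_compounds(
    compounds: Iterable[CompoundRecord] | DescriptorTable,
    config: ScreenConfig = ScreenConfig(),
) -> list[CompoundRecord]:
    """Keep compounds that are QC, blood-detectable, or have OB > threshold.

    The bioavailability comparison is strict (exactly the threshold fails the
    OB clause), and a missing OB value never satisfies it.
    """
    return [r for r in compounds if _passes(r, config)]


def enumerate_unknown_pairs(
    compound_ids: Sequence[str],
    disease_ids: Sequence[str],
    known_pairs: Iterable[PairLabel] = (),
) -> list[tuple[str, str]]:
    """All compound x disease pairs not already labeled in the benchmark."""
    if len(set(compound_ids)) != len(compound_ids):
        raise ValueError("duplicate compound ids")
    if len(set(disease_ids)) != len(disease_ids):
        raise ValueError("duplicate disease ids")
    known = {p.key for p in known_pairs}
    return [
        (c, d)
        for c in sorted(compound_ids)
        for d in sorted(disease_ids)
        if (c, d) not in known
    ]


def encode_pairs(
    pairs: Sequence[tuple[str, str]],
    compounds: DescriptorTable,
    diseases: DescriptorTable,
) -> np.ndarray:
    """Stack of [0, 1] image arrays for a pair list (normalized tables)."""
    missing = [
        pair
        for pair in pairs
        if pair[0] not in compounds.values.index or pair[1] not in diseases.values.index
    ]
    if missing:
        raise ValueError(
            f"{len(missing)} pairs reference entities without descriptor "
            f"vectors, e.g. {missing[:3]}"
        )
    comp_mat = compounds.values
    dis_mat = diseases.values
    images = np.empty(
        (len(pairs), compounds.n_features, diseases.n_features), dtype=np.float32
    )
    for i, (cid, did) in enumerate(pairs):
        m = build_matrix(
            comp_mat.loc[cid].to_numpy(), dis_mat.loc[did].to_numpy(), cid, did
        )
        images[i] = to_grayscale(m).pixels / 255.0
    return images


def screen(
    trained: TrainedModel,
    pairs: Sequence[tuple[str, str]],
    compounds: DescriptorTable,
    diseases: DescriptorTable,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Score every pair, rank by probability, and flag candidates.

    Descriptor tables must already carry the frozen training-set
    normalization.  Entries are sorted by descending probability with ties
    broken by (compound_id, disease_id) for a stable, reproducible order.
    """
    if not compounds.normalized or not diseases.normalized:
        raise ValueError("descriptor tables must be normalized before screening")
    images = encode_pairs(pairs, compounds, diseases)
    preds = predict(
        trained, images,
        compound_ids=[c for c, _ in pairs],
        disease_ids=[d for _, d in pairs],
    )
    frame = pd.DataFrame(
        {
            "compound_id": preds.compound_ids,
            "disease_id": preds.disease_ids,
            "probability": preds.probabilities,
        }
    )
    frame["candidate"] = frame["probability"] > config.candidate_cut
    frame = frame.sort_values(
        ["probability", "compound_id", "disease_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    summary = {
        "n_compounds": len({c for c, _ in pairs}),
        "n_pairs": len(pairs),
        "n_predicted_positive": int((frame["probability"] > 0.5).sum()),
        "n_candidates": int(frame["candidate"].sum()),
        "candidate_cut": config.candidate_cut,
    }
    return ScreenResult(entries=frame, summary=summary)


def write_screen_result(result: ScreenResult, csv_path: str | Path,
                        summary_path: str | Path | None = None) -> None:
    result.entries.to_csv(csv_path, index=False)
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(result.summary, indent=1))
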