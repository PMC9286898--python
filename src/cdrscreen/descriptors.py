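"""Descriptor tables for compounds and diseases, with min-max normalization.

A compound is described by a dense vector of molecular descriptors (the
reference pipeline used 5270 Dragon descriptors); a disease by a sparse
non-negative vector of symptom weights (322 symptom descriptors from the
human symptom-disease network).  Both arrive as delimited text with a header
row: the first column is the entity id, every remaining numeric column is a
feature.  Compound tables may additionally carry the screening annotation
columns ``is_qc``, ``is_blood`` and ``ob_percent``; these are kept apart from
the feature block.

Normalization is per-feature min-max to [0, 1], fitted once on a reference
(training) table and re-applied to new records with
:func:`apply_normalization` so that screened compounds are encoded on the
same scale as the benchmark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

Entity = Literal["compound", "disease"]

#: compound annotation columns that are not descriptor features
ANNOTATION_COLUMNS = ("name", "is_qc", "is_blood", "ob_percent")


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant (e.g. duplicate ids)."""


class ParseError(ValueError):
    """Raised when a delimited file cannot be parsed (e.g. ragged rows)."""


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    descriptors: np.ndarray
    name: str | None = None
    is_qc: bool = False
    is_blood: bool = False
    ob_percent: float | None = None


@dataclass(frozen=True)
class DiseaseRecord:
    disease_id: str
    symptoms: np.ndarray
    name: str | None = None


@dataclass
class DescriptorTable:
    """A set of entities sharing one feature space.

    ``values`` is an (n_records, n_features) float frame indexed by entity id;
    ``annotations`` holds any non-feature columns (compound screening flags).
    """

    entity: Entity
    values: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)
    normalized: bool = False
    norm_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate {self.entity} ids: {dupes}"
            )
        if self.normalized:
            if self.norm_params is None:
                raise ValidationError("normalized table lacks norm_params")
            vals = self.values.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValidationError("normalized table has values outside [0, 1]")
        elif self.norm_params is not None:
            raise ValidationError("norm_params present on an unnormalized table")

    @property
    def ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def feature_names(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def vector(self, entity_id: str) -> np.ndarray:
        """Feature vector for one entity id."""
        return self.values.loc[entity_id].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[CompoundRecord | DiseaseRecord]:
        for entity_id in self.values.index:
            vec = self.values.loc[entity_id].to_numpy(dtype=float)
            ann = (
                self.annotations.loc[entity_id]
                if entity_id in self.annotations.index
                else None
            )
            name = None if ann is None or "name" not in ann else ann["name"]
            if self.entity == "compound":
                ob = None
                if ann is not None and "ob_percent" in ann and pd.notna(ann["ob_percent"]):
                    ob = float(ann["ob_percent"])
                yield CompoundRecord(
                    compound_id=str(entity_id),
                    descriptors=vec,
                    name=name,
                    is_qc=bool(ann["is_qc"]) if ann is not None and "is_qc" in ann else False,
                    is_blood=bool(ann["is_blood"]) if ann is not None and "is_blood" in ann else False,
                    ob_percent=ob,
                )
            else:
                yield DiseaseRecord(disease_id=str(entity_id), symptoms=vec, name=name)


def _detect_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    for delim in ("\t", ";", ","):
        if delim in header:
            return delim
    return ","


def read_descriptor_table(
    path: str | Path,
    entity: Entity,
    delimiter: str | None = None,
) -> DescriptorTable:
    """Read a compound or disease table from delimited text.

    The header names the columns; the first column is the entity id.  Columns
    named in :data:`ANNOTATION_COLUMNS` become annotations, all other columns
    are parsed as float features.  Missing numeric cells are stored as NaN,
    never silently as zero.  Ragged rows raise :class:`ParseError` naming the
    offending line; duplicate ids raise :class:`ValidationError`.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    try:
        frame = pd.read_csv(
            path, sep=delimiter, header=0, dtype={0: str},
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: need an id column and at least one feature column")
    id_col = frame.columns[0]
    frame = frame.set_index(id_col)
    ann_cols = [c for c in frame.columns if c in ANNOTATION_COLUMNS]
    feat_cols = [c for c in frame.columns if c not in ANNOTATION_COLUMNS]
    try:
        values = frame[feat_cols].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric feature cell: {exc}") from exc
    annotations = frame[ann_cols].copy()
    for flag in ("is_qc", "is_blood"):
        if flag in annotations:
            annotations[flag] = annotations[flag].fillna(0).astype(bool)
    return DescriptorTable(entity=entity, values=values, annotations=annotations)


def write_descriptor_table(
    table: DescriptorTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write a table in the dialect :func:`read_descriptor_table` expects.

    Values are written at full ``repr`` precision so a read-back is
    bit-identical.
    """
    path = Path(path)
    frame = table.values.copy()
    if not table.annotations.empty:
        frame = pd.concat([table.annotations, frame], axis=1)
    id_name = "compound_id" if table.entity == "compound" else "disease_id"
    frame.index.name = id_name
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def normalize(
    table: DescriptorTable, missing: Literal["error", "median"] = "error"
) -> DescriptorTable:
    """Min-max rescale every feature column independently to [0, 1].

    ``x' = (x - min) / (max - min)``; a constant column maps to all zeros so
    the feature dimension (and hence the image geometry) is preserved.  The
    fitted per-feature ``(min, max)`` pairs are stored on the result so the
    identical transform can later be applied to unseen records.

    Missing cells are rejected by default; ``missing="median"`` fills each
    with its column median first (an explicit opt-in, since imputation changes
    the rendered images invisibly).
    """
    if table.normalized:
        raise ValidationError("table is already normalized")
    values = table.values.copy()
    if values.isna().any().any():
        if missing == "median":
            values = values.fillna(values.median())
        else:
            bad = values.columns[values.isna().any()].tolist()
            raise ValidationError(
                f"missing values in columns {bad}; pass missing='median' to fill"
            )
    mins = values.min()
    maxs = values.max()
    span = (maxs - mins).replace(0.0, 1.0)  # constant columns -> x - min = 0
    scaled = (values - mins) / span
    params = {c: (float(mins[c]), float(maxs[c])) for c in values.columns}
    return replace(
        table, values=scaled, normalized=True, norm_params=params
    )


def apply_normalization(
    table: DescriptorTable, params: Mapping[str, tuple[float, float]]
) -> DescriptorTable:
    """Apply previously fitted min-max parameters to a new table.

    Out-of-range values (beyond the training min or max) are clipped to
    [0, 1]; this keeps screened compounds on the training scale.
    """
    if table.normalized:
        raise ValidationError("table is already normalized")
    missing_cols = [c for c in table.feature_names if c not in params]
    extra = [c for c in params if c not in table.feature_names]
    if missing_cols or extra:
        raise ValidationError(
            f"normalization params do not match features "
            f"(missing={missing_cols[:5]}, extra={extra[:5]})"
        )
    values = table.values.copy()
    for col in values.columns:
        lo, hi = params[col]
        span = (hi - lo) or 1.0
        values[col] = ((values[col] - lo) / span).clip(0.0, 1.0)
    return replace(
        table,
        values=values,
        normalized=True,
        norm_params={c: (float(v[0]), float(v[1])) for c, v in params.items()},
    )


def save_norm_params(
    params: Mapping[str, tuple[float, float]], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({k: [v[0], v[1]] for k, v in params.items()}, indent=1)
    )


def load_norm_params(path: str | Path) -> dict[str, tuple[float, float]]:
    raw = json.loads(Path(path).read_text())
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
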