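"""Layered tabular data: reading, alignment, and skewness-reducing transforms.

A *layer* is a CSV table whose rows are examples (keyed by a shared ID
column) and whose columns are nominal or numeric attributes.  Multiple
layers over the same examples form a :class:`LayeredDataset`.  Numeric
attributes may carry a skewness-reducing transform (``log``, ``logit`` or
``reciprocal``), selected manually per attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Tokens treated as missing on read (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan"})

NUMERIC = "numeric"
NOMINAL = "nominal"
TRANSFORMS = ("none", "log", "logit", "reciprocal")


@dataclass(frozen=True)
class AttributeSpec:
    """Declared type and optional transform of one attribute column."""

    name: str
    kind: str  # "numeric" | "nominal"
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, NOMINAL):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform != "none" and self.kind != NUMERIC:
            raise ValueError(
                f"attribute {self.name!r}: transform {self.transform!r} "
                "requires a numeric attribute"
            )


@dataclass
class DataLayer:
    """One attribute layer: examples x mixed nominal/numeric attributes.

    ``data`` is indexed by example ID (opaque strings, never used as
    features); numeric columns are float with NaN for missing, nominal
    columns are object dtype with NaN for missing.
    """

    name: str
    data: pd.DataFrame
    attributes: list[AttributeSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError(f"layer {self.name!r}: need at least one row and column")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"layer {self.name!r}: duplicate example ID {dup!r}")
        if not self.attributes:
            self.attributes = [
                AttributeSpec(c, NUMERIC if pd.api.types.is_numeric_dtype(self.data[c]) else NOMINAL)
                for c in self.data.columns
            ]
        names = [a.name for a in self.attributes]
        if names != list(self.data.columns):
            raise ValueError(f"layer {self.name!r}: attribute specs do not match columns")

    @property
    def example_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def n_examples(self) -> int:
        return self.data.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.data.shape[1]

    def kind_of(self, attribute: str) -> str:
        for a in self.attributes:
            if a.name == attribute:
                return a.kind
        raise KeyError(attribute)

    def numeric_attributes(self) -> list[str]:
        return [a.name for a in self.attributes if a.kind == NUMERIC]

    def nominal_attributes(self) -> list[str]:
        return [a.name for a in self.attributes if a.kind == NOMINAL]


@dataclass
class LayeredDataset:
    """Ordered layers sharing identical example IDs in identical order."""

    layers: list[DataLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a dataset needs at least one layer")
        ids0 = self.layers[0].example_ids
        for lay in self.layers[1:]:
            if lay.example_ids != ids0:
                raise ValueError(
                    f"layer {lay.name!r} does not share example IDs with "
                    f"layer {self.layers[0].name!r}"
                )
        seen: dict[str, str] = {}
        for lay in self.layers:
            for a in lay.attributes:
                if a.name in seen:
                    raise ValueError(
                        f"attribute {a.name!r} appears in layers "
                        f"{seen[a.name]!r} and {lay.name!r}"
                    )
                seen[a.name] = lay.name

    @property
    def example_ids(self) -> list[str]:
        return self.layers[0].example_ids


def _is_missing_token(tok: str) -> bool:
    return tok.strip().lower() in MISSING_TOKENS


def read_layer(
    path: str | Path,
    type_overrides: Mapping[str, str] | None = None,
    id_column: str = "id",
    name: str | None = None,
) -> DataLayer:
    """Read one layer from CSV, detecting attribute types.

    A column with any non-numeric, non-missing token becomes nominal;
    ``type_overrides`` (attribute name -> "numeric"/"nominal") wins over
    detection.  Missing tokens ("", "NA", "NaN", case-insensitive) become
    NaN.  Duplicate IDs and empty files raise ``ValueError``.
    """
    path = Path(path)
    overrides = dict(type_overrides or {})
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if id_column not in raw.columns:
        raise ValueError(f"{path}: no ID column {id_column!r}")
    ids = raw[id_column].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate example ID {dup.iloc[0]!r}")
    body = raw.drop(columns=[id_column])
    if body.shape[1] == 0:
        raise ValueError(f"{path}: no attribute columns")
    body.index = pd.Index(ids, name=id_column)

    cols: dict[str, pd.Series] = {}
    specs: list[AttributeSpec] = []
    for col in body.columns:
        tokens = body[col]
        miss = tokens.map(_is_missing_token)
        numeric = pd.to_numeric(tokens.where(~miss), errors="coerce")
        detected = NUMERIC if bool((miss | numeric.notna()).all()) else NOMINAL
        kind = overrides.get(col, detected)
        if kind == NUMERIC:
            if (numeric.isna() & ~miss).any():
                bad = tokens[numeric.isna() & ~miss].iloc[0]
                raise ValueError(
                    f"{path}: column {col!r} declared numeric but holds {bad!r}"
                )
            cols[col] = numeric.astype(float)
        else:
            cols[col] = tokens.where(~miss).astype(object)
        specs.append(AttributeSpec(col, kind))
    frame = pd.DataFrame(cols, index=body.index)
    return DataLayer(name or path.stem, frame, specs)


def write_layer(layer: DataLayer, path: str | Path, id_column: str = "id") -> None:
    """Write a layer back to CSV (missing cells as empty fields)."""
    out = layer.data.copy()
    out.index.name = id_column
    out.to_csv(path, na_rep="")


def align_layers(layers: Sequence[DataLayer]) -> LayeredDataset:
    """Restrict all layers to the IDs present in every layer.

    Kept IDs follow the order of the first layer; dropped IDs are logged.
    An empty intersection raises ``ValueError``.
    """
    if not layers:
        raise ValueError("no layers given")
    common = set(layers[0].example_ids)
    for lay in layers[1:]:
        common &= set(lay.example_ids)
    if not common:
        raise ValueError("no example IDs shared by all layers")
    order = [i for i in layers[0].example_ids if i in common]
    aligned = []
    for lay in layers:
        dropped = sorted(set(lay.example_ids) - common)
        if dropped:
            log.info("layer %s: dropping %d unmatched IDs: %s",
                     lay.name, len(dropped), ", ".join(dropped[:10]))
        aligned.append(DataLayer(lay.name, lay.data.loc[order], list(lay.attributes)))
    return LayeredDataset(aligned)


def transform_variable(
    values: Sequence[float] | np.ndarray,
    method: str,
    name: str = "variable",
) -> np.ndarray:
    """Apply a skewness-reducing transform element-wise; NaN stays NaN.

    ``log`` needs values > 0, ``logit`` values in (0, 1), ``reciprocal``
    values != 0; violations raise ``ValueError`` naming the attribute and
    the offending value.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if method == "none":
        return x.copy()
    if method == "log":
        bad = ok & (x <= 0)
        if bad.any():
            raise ValueError(f"{name}: log undefined for value {x[bad][0]!r}")
        out = np.where(ok, np.log(np.where(ok, x, 1.0)), np.nan)
    elif method == "logit":
        bad = ok & ((x <= 0) | (x >= 1))
        if bad.any():
            raise ValueError(f"{name}: logit needs values in (0, 1), got {x[bad][0]!r}")
        safe = np.where(ok, x, 0.5)
        out = np.where(ok, np.log(safe / (1.0 - safe)), np.nan)
    elif method == "reciprocal":
        bad = ok & (x == 0)
        if bad.any():
            raise ValueError(f"{name}: reciprocal undefined for value 0.0")
        out = np.where(ok, 1.0 / np.where(ok, x, 1.0), np.nan)
    else:
        raise ValueError(f"unknown transform {method!r}")
    return out


def apply_transforms(layer: DataLayer, transforms: Mapping[str, str]) -> DataLayer:
    """Return a copy of ``layer`` with the given per-attribute transforms applied."""
    frame = layer.data.copy()
    specs = []
    for spec in layer.attributes:
        method = transforms.get(spec.name, "none")
        if method != "none":
            if spec.kind != NUMERIC:
                raise ValueError(f"{spec.name!r}: cannot transform a nominal attribute")
            frame[spec.name] = transform_variable(
                frame[spec.name].to_numpy(), method, name=spec.name
            )
            specs.append(replace(spec, transform=method))
        else:
            specs.append(spec)
    return DataLayer(layer.name, frame, specs)
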