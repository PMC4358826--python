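"""Reading, validation and normalization of environmental object tables.

An *object table* is a flat collection of physical objects, each with a
measured volume (cm^3), weight (g) and a derived density (g/cm^3), plus
class labels: which dataset it belongs to (D1..D5), whether it is
artificial or natural, and whether it is liftable.

Volumes either come directly from a volume column or are derived from
length x width x height bounding-box dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DATASETS = ("D1", "D2", "D3", "D4", "D5")
CATEGORIES = ("artificial", "natural")
VOLUME_METHODS = ("ruler_geometry", "box_dims", "mesh_scan")

#: class labels implied by each dataset id: (category, liftable)
DATASET_CLASSES = {
    "D1": ("artificial", True),
    "D2": ("artificial", True),
    "D3": ("artificial", True),
    "D4": ("natural", True),
    "D5": ("artificial", False),
}

#: multiplicative factors converting declared units to cm^3 / g
VOLUME_UNIT_TO_CM3 = {
    "cm3": 1.0,
    "mm3": 1e-3,
    "m3": 1e6,
    "in3": 16.387064,
    "l": 1000.0,
    "ml": 1.0,
}
LENGTH_UNIT_TO_CM = {
    "cm": 1.0,
    "mm": 0.1,
    "m": 100.0,
    "in": 2.54,
}
WEIGHT_UNIT_TO_G = {
    "g": 1.0,
    "kg": 1000.0,
    "mg": 1e-3,
    "oz": 28.349523125,
    "lb": 453.59237,
}

#: fixed column order of the normalized CSV format
NORMALIZED_COLUMNS = [
    "id",
    "name",
    "dataset",
    "category",
    "liftable",
    "volume_cm3",
    "weight_g",
    "density_g_cm3",
    "volume_method",
]


class SchemaError(ValueError):
    """A mandatory column is missing or the schema is inconsistent."""


def volume_from_dims(length: float, width: float, height: float) -> float:
    """Bounding-box volume (cm^3) from three dimensions in cm.

    Invariant under permutation of the arguments.

    Raises
    ------
    ValueError
        If any dimension is not strictly positive.
    """
    if length <= 0 or width <= 0 or height <= 0:
        raise ValueError(
            f"dimensions must be strictly positive, got ({length}, {width}, {height})"
        )
    return length * width * height


def compute_density(weight: float, volume: float) -> float:
    """Density d = w/V in g/cm^3.

    Raises
    ------
    ValueError
        If volume is not strictly positive.
    """
    if volume <= 0:
        raise ValueError(f"volume must be strictly positive, got {volume}")
    return weight / volume


@dataclass(frozen=True)
class ObjectRecord:
    """One physical object with measured volume/weight and class labels."""

    id: str
    name: str
    dataset: str
    category: str
    liftable: bool
    volume: float  # cm^3
    weight: float  # g
    volume_method: str = "box_dims"

    def __post_init__(self) -> None:
        if self.dataset not in DATASETS:
            raise ValueError(f"unknown dataset {self.dataset!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.volume_method not in VOLUME_METHODS:
            raise ValueError(f"unknown volume_method {self.volume_method!r}")
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        cat, lift = DATASET_CLASSES[self.dataset]
        if (self.category, self.liftable) != (cat, lift):
            raise ValueError(
                f"dataset {self.dataset} implies class ({cat}, liftable={lift}), "
                f"got ({self.category}, liftable={self.liftable})"
            )

    @property
    def density(self) -> float:
        """Derived density w/V in g/cm^3."""
        return compute_density(self.weight, self.volume)


@dataclass
class ObjectTable:
    """Ordered collection of :class:`ObjectRecord` with provenance."""

    records: list[ObjectRecord]
    provenance: str = "in-memory"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ObjectRecord]:
        return iter(self.records)

    def subset(self, predicate) -> "ObjectTable":
        """New table with the records for which ``predicate(record)`` holds."""
        return ObjectTable(
            [r for r in self.records if predicate(r)],
            provenance=f"{self.provenance} (filtered)",
        )

    def by_dataset(self, dataset: str) -> "ObjectTable":
        return self.subset(lambda r: r.dataset == dataset)

    def to_frame(self) -> pd.DataFrame:
        """Normalized DataFrame with the fixed column layout."""
        rows = [
            {
                "id": r.id,
                "name": r.name,
                "dataset": r.dataset,
                "category": r.category,
                "liftable": r.liftable,
                "volume_cm3": r.volume,
                "weight_g": r.weight,
                "density_g_cm3": r.density,
                "volume_method": r.volume_method,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=NORMALIZED_COLUMNS)


def concat_tables(tables: Iterable[ObjectTable], provenance: str = "pooled") -> ObjectTable:
    """Pool several tables into one; ids must remain unique."""
    records: list[ObjectRecord] = []
    for t in tables:
        records.extend(t.records)
    return ObjectTable(records, provenance=provenance)


@dataclass(frozen=True)
class ColumnSchema:
    """Maps input CSV columns onto the object-record fields.

    Exactly one of ``volume`` / (``length``, ``width``, ``height``) routes
    must be fully specified.  Unit declarations apply per file and are
    converted at parse time.
    """

    weight: str
    volume: str | None = None
    length: str | None = None
    width: str | None = None
    height: str | None = None
    id: str | None = None
    name: str | None = None
    dataset: str | None = None  # column holding D1..D5 labels
    default_dataset: str | None = None  # used when no dataset column
    volume_unit: str = "cm3"
    length_unit: str = "cm"
    weight_unit: str = "g"
    volume_method: str | None = None  # override; default inferred

    def __post_init__(self) -> None:
        has_volume = self.volume is not None
        dims = (self.length, self.width, self.height)
        has_dims = all(d is not None for d in dims)
        if not has_volume and not has_dims:
            raise SchemaError(
                "schema must map a volume column or all of length/width/height"
            )
        if self.volume_unit not in VOLUME_UNIT_TO_CM3:
            raise SchemaError(f"unknown volume unit {self.volume_unit!r}")
        if self.length_unit not in LENGTH_UNIT_TO_CM:
            raise SchemaError(f"unknown length unit {self.length_unit!r}")
        if self.weight_unit not in WEIGHT_UNIT_TO_G:
            raise SchemaError(f"unknown weight unit {self.weight_unit!r}")
        if self.dataset is None and self.default_dataset is None:
            raise SchemaError("schema needs a dataset column or a default_dataset")

    @property
    def uses_dims(self) -> bool:
        return self.volume is None


def _infer_volume_method(schema: ColumnSchema, dataset: str) -> str:
    if schema.volume_method is not None:
        return schema.volume_method
    if schema.uses_dims:
        return "box_dims"
    return {"D1": "ruler_geometry", "D2": "box_dims", "D5": "box_dims"}.get(
        dataset, "mesh_scan"
    )


def load_object_table(path: str | Path, schema: ColumnSchema) -> ObjectTable:
    """Load a CSV (or XLSX) object table, deriving volume and density.

    Rows with missing or non-positive volume/weight (or dimensions) are
    dropped and logged, not imputed.

    Raises
    ------
    SchemaError
        If a mapped column is absent from the file.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)

    needed = [schema.weight]
    needed += [schema.volume] if not schema.uses_dims else [
        schema.length, schema.width, schema.height
    ]
    for col in (schema.id, schema.name, schema.dataset):
        if col is not None:
            needed.append(col)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")

    vunit = VOLUME_UNIT_TO_CM3[schema.volume_unit]
    lunit = LENGTH_UNIT_TO_CM[schema.length_unit]
    wunit = WEIGHT_UNIT_TO_G[schema.weight_unit]

    records: list[ObjectRecord] = []
    n_dropped = 0
    for i, row in df.iterrows():
        rid = str(row[schema.id]) if schema.id else f"{path.stem}-{i}"
        name = str(row[schema.name]) if schema.name else rid
        dataset = (
            str(row[schema.dataset]) if schema.dataset else schema.default_dataset
        )
        if dataset not in DATASETS:
            logger.warning("%s row %s: unknown dataset %r, dropped", path.name, i, dataset)
            n_dropped += 1
            continue
        try:
            weight = float(row[schema.weight]) * wunit
            if schema.uses_dims:
                dims = [float(row[c]) * lunit
                        for c in (schema.length, schema.width, schema.height)]
                volume = volume_from_dims(*dims)
            else:
                volume = float(row[schema.volume]) * vunit
            if not (volume > 0 and weight > 0):
                raise ValueError(f"non-positive volume/weight ({volume}, {weight})")
            category, liftable = DATASET_CLASSES[dataset]
            records.append(
                ObjectRecord(
                    id=rid,
                    name=name,
                    dataset=dataset,
                    category=category,
                    liftable=liftable,
                    volume=volume,
                    weight=weight,
                    volume_method=_infer_volume_method(schema, dataset),
                )
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s row %s: rejected (%s)", path.name, i, exc)
            n_dropped += 1
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s)", path.name, n_dropped)
    return ObjectTable(records, provenance=f"{path.name} ({len(records)} rows)")


#: schema of the normalized CSV this package writes
NORMALIZED_SCHEMA = ColumnSchema(
    weight="weight_g",
    volume="volume_cm3",
    id="id",
    name="name",
    dataset="dataset",
)


def write_object_table(table: ObjectTable, path: str | Path) -> None:
    """Write the normalized CSV layout (see :data:`NORMALIZED_COLUMNS`)."""
    table.to_frame().to_csv(path, index=False)


def read_object_table(path: str | Path) -> ObjectTable:
    """Read a normalized CSV written by :func:`write_object_table`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in NORMALIZED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: not a normalized object CSV, missing {missing}")
    records = [
        ObjectRecord(
            id=str(row["id"]),
            name=str(row["name"]),
            dataset=str(row["dataset"]),
            category=str(row["category"]),
            liftable=bool(row["liftable"]),
            volume=float(row["volume_cm3"]),
            weight=float(row["weight_g"]),
            volume_method=str(row["volume_method"]),
        )
        for _, row in df.iterrows()
    ]
    return ObjectTable(records, provenance=path.name)
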