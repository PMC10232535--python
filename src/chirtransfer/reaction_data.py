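"""Reaction records, physical-organic descriptor tables and the reaction encoding.

A reaction is described by three molecular entities — an indole substrate, an
alkene coupling partner and a chiral carboxylic acid (CCA) co-catalyst — plus
the reaction temperature.  Each entity class carries a fixed-length vector of
precomputed physical-organic descriptors (Sterimol-type steric lengths in Å,
atomic charges in units of *e*, and other dimensionless features).  The full
reaction encoding is the concatenation

    indole block ‖ alkene block ‖ CCA block ‖ temperature,

which under the default schema (35 + 6 + 66 + 1) is 108-dimensional.

Selectivity is handled on the free-energy scale: an enantiomeric excess *ee*
at temperature *T* maps to the free-energy difference between the competing
enantiodetermining transition states,

    ΔΔG = R·T·ln((1 + ee) / (1 − ee))   [kcal/mol],

with the inverse ee = tanh(ΔΔG / (2·R·T)).  Regression is done on ΔΔG, which
is additive and unbounded, rather than on the saturating ee scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EXPECTED_WIDTHS",
    "EE_MAX",
    "ee_to_ddg",
    "ddg_to_ee",
    "DescriptorTable",
    "load_descriptor_table",
    "ReactionRecord",
    "load_reaction_records",
    "EncodedReaction",
    "encode_reaction",
    "encode_dataset",
    "EncodedDataset",
    "ValidationReport",
    "validate_dataset",
]

#: Molar gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.98720425e-3

#: Default descriptor-vector lengths per entity class.
EXPECTED_WIDTHS = {"indole": 35, "alkene": 6, "cca": 66}

#: Enantiomeric excesses at or above this are rejected rather than clamped:
#: ΔΔG diverges as ee → 1 and a silently saturated target corrupts regression.
EE_MAX = 0.999

_ENTITY_CLASSES = tuple(EXPECTED_WIDTHS)


def ee_to_ddg(ee, temperature):
    """Convert (signed) enantiomeric excess to ΔΔG in kcal/mol.

    Parameters
    ----------
    ee : float or array-like
        Enantiomeric excess as a fraction, ``|ee| < 1``.  The sign encodes
        which enantiomer is major; unsigned data simply use [0, 1).
    temperature : float
        Absolute temperature in kelvin, > 0.

    Returns
    -------
    float or ndarray
        ΔΔG = R·T·ln((1+ee)/(1−ee)), odd and strictly increasing in ``ee``.
    """
    ee_arr = np.asarray(ee, dtype=float)
    if np.any(np.abs(ee_arr) >= 1.0):
        raise ValueError("ee must satisfy |ee| < 1; ΔΔG diverges at ee = 1")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive (got {temperature} K)")
    out = GAS_CONSTANT_KCAL * temperature * np.log((1.0 + ee_arr) / (1.0 - ee_arr))
    return float(out) if np.isscalar(ee) or out.ndim == 0 else out


def ddg_to_ee(ddg, temperature):
    """Convert ΔΔG (kcal/mol) to signed enantiomeric excess, ee = tanh(ΔΔG/2RT).

    Total function: any finite ΔΔG maps into (−1, 1).  The reported e.e. is
    the absolute value.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive (got {temperature} K)")
    ddg_arr = np.asarray(ddg, dtype=float)
    out = np.tanh(ddg_arr / (2.0 * GAS_CONSTANT_KCAL * temperature))
    return float(out) if np.isscalar(ddg) or out.ndim == 0 else out


@dataclass(frozen=True)
class DescriptorTable:
    """Entity-ID → fixed-length named descriptor vector for one entity class.

    ``frame`` is indexed by entity id; columns are descriptor names in their
    canonical order.  All values are finite floats.
    """

    entity_class: str
    frame: pd.DataFrame

    def __post_init__(self):
        if self.entity_class not in _ENTITY_CLASSES:
            raise ValueError(
                f"unknown entity class {self.entity_class!r}; "
                f"expected one of {_ENTITY_CLASSES}"
            )
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(
                f"duplicate entity_id(s) in {self.entity_class} table: {dupes}"
            )
        values = self.frame.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite descriptor in {self.entity_class} table at "
                f"row {self.frame.index[bad[0]]!r}, column "
                f"{self.frame.columns[bad[1]]!r}"
            )

    @property
    def width(self) -> int:
        return self.frame.shape[1]

    @property
    def entity_ids(self) -> list:
        return list(self.frame.index)

    def vector(self, entity_id: str) -> np.ndarray:
        """Descriptor vector for one entity; raises KeyError naming the id."""
        try:
            return self.frame.loc[entity_id].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(
                f"unknown {self.entity_class} id {entity_id!r}"
            ) from None

    def __contains__(self, entity_id) -> bool:
        return entity_id in self.frame.index

    def column_names(self) -> list[str]:
        return [f"{self.entity_class}:{c}" for c in self.frame.columns]


def load_descriptor_table(
    path, entity_class: str, expected_width: int | None = None
) -> DescriptorTable:
    """Read a descriptor CSV (entity_id in the first column, header row).

    ``expected_width`` defaults to the class default (35/6/66).  A file whose
    width differs from the default is accepted with a warning — descriptor
    schemas are data-driven — but ragged rows or non-numeric cells are errors
    located by row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"descriptor table not found: {path}")
    raw = pd.read_csv(path, index_col=0)
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: no descriptor columns")
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric value in row {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = raw.index[converted.isna().to_numpy().argmax()]
            raise ValueError(f"{path}: missing value in row {row!r}, column {col!r}")
        raw[col] = converted.astype(float)
    expected = expected_width if expected_width is not None else EXPECTED_WIDTHS[entity_class]
    if raw.shape[1] != expected:
        import warnings

        warnings.warn(
            f"{path}: {entity_class} table has {raw.shape[1]} descriptor "
            f"columns, expected {expected}; proceeding with the file's schema",
            stacklevel=2,
        )
    raw.index = raw.index.astype(str)
    return DescriptorTable(entity_class=entity_class, frame=raw)


@dataclass(frozen=True)
class ReactionRecord:
    """One selectivity measurement: entity ids, temperature and observed e.e.

    ``ddg_exp`` is derived from ``ee_observed`` at construction and cached;
    e.e. is stored unsigned in [0, EE_MAX) under the convention that the major
    enantiomer is consistent across the dataset.
    """

    reaction_id: str
    domain: str  # "source" or "target"
    indole_id: str
    alkene_id: str
    cca_id: str
    temperature: float  # kelvin
    ee_observed: float  # fraction in [0, EE_MAX)
    ddg_exp: float = field(init=False)  # kcal/mol, derived

    def __post_init__(self):
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be 'source' or 'target', got {self.domain!r}")
        if self.temperature <= 0:
            raise ValueError(
                f"record {self.reaction_id}: temperature must be > 0 K "
                f"(got {self.temperature})"
            )
        if not (0.0 <= self.ee_observed < EE_MAX):
            raise ValueError(
                f"record {self.reaction_id}: ee must lie in [0, {EE_MAX}) "
                f"(got {self.ee_observed}); near-unity ee is rejected, not clamped"
            )
        object.__setattr__(
            self, "ddg_exp", ee_to_ddg(self.ee_observed, self.temperature)
        )


def load_reaction_records(path, domain: str) -> list[ReactionRecord]:
    """Read reaction records from CSV.

    Required columns: ``reaction_id, indole_id, alkene_id, cca_id,
    temperature_k, ee`` (ee as a fraction in [0, 1)).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reaction record file not found: {path}")
    df = pd.read_csv(path)
    required = {"reaction_id", "indole_id", "alkene_id", "cca_id", "temperature_k", "ee"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ReactionRecord(
                reaction_id=str(row.reaction_id),
                domain=domain,
                indole_id=str(row.indole_id),
                alkene_id=str(row.alkene_id),
                cca_id=str(row.cca_id),
                temperature=float(row.temperature_k),
                ee_observed=float(row.ee),
            )
        )
    return records


@dataclass(frozen=True)
class EncodedReaction:
    """Concatenated descriptor vector with provenance column labels."""

    vector: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self):
        vec = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", vec)
        if vec.ndim != 1:
            raise ValueError("encoding must be a 1-D vector")
        if len(self.column_names) != vec.shape[0]:
            raise ValueError("column_names length must match vector length")

    def __len__(self) -> int:
        return int(self.vector.shape[0])


def encode_reaction(
    record: ReactionRecord, tables: Mapping[str, DescriptorTable]
) -> EncodedReaction:
    """Assemble the fixed-block-order encoding for one reaction.

    Block order is indole ‖ alkene ‖ cca ‖ temperature, identical for every
    encoding produced from the same tables.  Unknown entity ids raise a
    KeyError naming the class and the id.
    """
    blocks, names = [], []
    for cls, attr in (("indole", "indole_id"), ("alkene", "alkene_id"), ("cca", "cca_id")):
        table = tables[cls]
        blocks.append(table.vector(getattr(record, attr)))
        names.extend(table.column_names())
    blocks.append(np.array([record.temperature]))
    names.append("temperature_K")
    return EncodedReaction(vector=np.concatenate(blocks), column_names=tuple(names))


@dataclass(frozen=True)
class EncodedDataset:
    """A design matrix with ΔΔG targets, ready for regression.

    ``X`` is (n_records, n_features) in the fixed block order, ``y`` the
    experimental ΔΔG in kcal/mol.
    """

    X: np.ndarray
    y: np.ndarray
    reaction_ids: tuple[str, ...]
    column_names: tuple[str, ...]

    def __post_init__(self):
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.reaction_ids):
            raise ValueError("X, y and reaction_ids must agree on record count")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("X width must match column_names")

    @property
    def n(self) -> int:
        return int(self.X.shape[0])


def encode_dataset(
    records: Sequence[ReactionRecord], tables: Mapping[str, DescriptorTable]
) -> EncodedDataset:
    """Encode a list of records into a design matrix plus ΔΔG targets."""
    if not records:
        raise ValueError("cannot encode an empty record list")
    encoded = [encode_reaction(r, tables) for r in records]
    names = encoded[0].column_names
    for enc in encoded[1:]:
        if enc.column_names != names:
            raise ValueError("inconsistent encoding schema across records")
    return EncodedDataset(
        X=np.vstack([e.vector for e in encoded]),
        y=np.array([r.ddg_exp for r in records]),
        reaction_ids=tuple(r.reaction_id for r in records),
        column_names=names,
    )


@dataclass
class ValidationReport:
    """Issues found in a record set; the dataset is accepted iff empty."""

    issues: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, kind: str, reaction_id: str, detail: str):
        self.issues.append({"kind": kind, "reaction_id": reaction_id, "detail": detail})

    def to_json(self) -> str:
        return json.dumps({"ok": self.ok, "issues": self.issues}, indent=2)


def validate_dataset(
    records: Iterable[ReactionRecord], tables: Mapping[str, DescriptorTable]
) -> ValidationReport:
    """Check id resolvability, e.e. range and reaction_id uniqueness.

    Returns a report rather than raising: callers decide whether a non-empty
    report aborts the run.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for rec in records:
        if rec.reaction_id in seen:
            report.add("duplicate_reaction_id", rec.reaction_id, "reaction_id reused")
        seen.add(rec.reaction_id)
        for cls, eid in (
            ("indole", rec.indole_id),
            ("alkene", rec.alkene_id),
            ("cca", rec.cca_id),
        ):
            if eid not in tables[cls]:
                report.add(
                    "unknown_entity",
                    rec.reaction_id,
                    f"{cls} id {eid!r} not in descriptor table",
                )
        # Range re-check covers records built by bypassing the constructor
        # (e.g. loaded from an external tool's output).
        if not (0.0 <= rec.ee_observed < EE_MAX):
            report.add(
                "ee_out_of_range",
                rec.reaction_id,
                f"ee {rec.ee_observed} outside [0, {EE_MAX})",
            )
        if not math.isfinite(rec.temperature) or rec.temperature <= 0:
            report.add("bad_temperature", rec.reaction_id, f"T = {rec.temperature} K")
    return report
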