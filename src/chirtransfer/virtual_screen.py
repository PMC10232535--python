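"""Combinatorial CCA library enumeration, screening and ranking.

Candidate C2-symmetric chiral carboxylic acids are enumerated as the full
Cartesian product of backbone variants × N-substituents.  Each candidate
resolves to a precomputed descriptor vector (default: a lookup table keyed by
the pair; alternatively composed from backbone-block and substituent-block
sub-tables).  Every candidate is encoded with a fixed substrate context
(indole, alkene, temperature), scored with the transfer model, converted to
predicted e.e., and ranked.

Ranking is by descending predicted e.e. — identical to ranking by predicted
ΔΔG, since the conversion is strictly monotone — with candidate_id as the
final lexicographic tie-break so Top-k is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .base_model import BaseModel, predict_base
from .delta_transfer import TransferModel, predict_transfer
from .reaction_data import DescriptorTable, ddg_to_ee

__all__ = [
    "CandidateCCA",
    "pair_table_source",
    "compositional_source",
    "enumerate_candidates",
    "ScreeningContext",
    "ScreeningEntry",
    "ScreeningResult",
    "screen",
    "top_k",
    "bin_distribution",
]


@dataclass(frozen=True)
class CandidateCCA:
    """One candidate catalyst: backbone × substituent with its descriptors."""

    candidate_id: str
    backbone_id: str
    substituent_id: str
    descriptor_vector: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "descriptor_vector", np.asarray(self.descriptor_vector, dtype=float)
        )


DescriptorSource = Callable[[str, str], np.ndarray]


def pair_table_source(frame: pd.DataFrame) -> DescriptorSource:
    """Descriptor source backed by a per-pair lookup table.

    ``frame`` needs ``backbone_id`` and ``substituent_id`` columns; the
    remaining numeric columns are the candidate's descriptor vector.
    """
    for col in ("backbone_id", "substituent_id"):
        if col not in frame.columns:
            raise ValueError(f"candidate table needs a {col!r} column")
    desc_cols = [c for c in frame.columns if c not in ("backbone_id", "substituent_id")]
    indexed = frame.set_index(["backbone_id", "substituent_id"])[desc_cols]
    if indexed.index.has_duplicates:
        raise ValueError("candidate table has duplicate (backbone, substituent) pairs")

    def source(backbone_id: str, substituent_id: str) -> np.ndarray:
        try:
            return indexed.loc[(backbone_id, substituent_id)].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(
                f"no descriptors for candidate pair "
                f"({backbone_id!r}, {substituent_id!r})"
            ) from None

    return source


def compositional_source(
    backbone_table: pd.DataFrame, substituent_table: pd.DataFrame
) -> DescriptorSource:
    """Descriptor source assembling [backbone block ‖ substituent block].

    Both tables are indexed by their part id; the candidate vector is the
    concatenation of the two blocks, so its length is the sum of the block
    widths.
    """

    def source(backbone_id: str, substituent_id: str) -> np.ndarray:
        try:
            b = backbone_table.loc[backbone_id].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"unknown backbone id {backbone_id!r}") from None
        try:
            s = substituent_table.loc[substituent_id].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"unknown substituent id {substituent_id!r}") from None
        return np.concatenate([b, s])

    return source


def enumerate_candidates(
    backbones: Sequence[str],
    substituents: Sequence[str],
    descriptor_source: DescriptorSource,
) -> list[CandidateCCA]:
    """Full Cartesian product backbones × substituents, |B|·|S| candidates."""
    if not backbones or not substituents:
        raise ValueError("backbone and substituent lists must be non-empty")
    candidates = []
    for b in backbones:
        for s in substituents:
            candidates.append(
                CandidateCCA(
                    candidate_id=f"{b}|{s}",
                    backbone_id=str(b),
                    substituent_id=str(s),
                    descriptor_vector=descriptor_source(str(b), str(s)),
                )
            )
    return candidates


@dataclass(frozen=True)
class ScreeningContext:
    """The fixed substrate pair and temperature shared by every candidate."""

    indole_id: str
    alkene_id: str
    temperature: float  # kelvin


@dataclass(frozen=True)
class ScreeningEntry:
    candidate_id: str
    backbone_id: str
    substituent_id: str
    ddg_pred: float  # kcal/mol
    ee_pred: float  # fraction, |tanh(ddg/2RT)|
    rank: int


@dataclass(frozen=True)
class ScreeningResult:
    """Ranked screen of one candidate library in one substrate context."""

    context: ScreeningContext
    entries: tuple[ScreeningEntry, ...]

    @property
    def n(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "candidate_id": e.candidate_id,
                    "backbone_id": e.backbone_id,
                    "substituent_id": e.substituent_id,
                    "ddg_pred_kcal_mol": e.ddg_pred,
                    "ee_pred": e.ee_pred,
                    "rank": e.rank,
                }
                for e in self.entries
            ]
        )


def screen(
    model: TransferModel | BaseModel,
    candidates: Sequence[CandidateCCA],
    context: ScreeningContext,
    tables: Mapping[str, DescriptorTable],
) -> ScreeningResult:
    """Predict every candidate's selectivity in the given context and rank.

    Accepts either the composite transfer model or a plain base model (the
    latter gives the uncorrected, source-SPR-only screen).  Deterministic:
    same model and inputs yield the same ranked list.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    indole_vec = tables["indole"].vector(context.indole_id)
    alkene_vec = tables["alkene"].vector(context.alkene_id)
    rows = []
    for cand in candidates:
        vec = np.concatenate(
            [indole_vec, alkene_vec, cand.descriptor_vector, [context.temperature]]
        )
        if isinstance(model, TransferModel):
            ddg = predict_transfer(model, vec)
        else:
            ddg = predict_base(model, vec)
        ee = abs(ddg_to_ee(ddg, context.temperature))
        rows.append((cand, ddg, ee))
    # Descending predicted e.e.; candidate_id breaks exact ties reproducibly.
    rows.sort(key=lambda t: (-t[2], t[0].candidate_id))
    entries = tuple(
        ScreeningEntry(
            candidate_id=cand.candidate_id,
            backbone_id=cand.backbone_id,
            substituent_id=cand.substituent_id,
            ddg_pred=ddg,
            ee_pred=ee,
            rank=i + 1,
        )
        for i, (cand, ddg, ee) in enumerate(rows)
    )
    return ScreeningResult(context=context, entries=entries)


def top_k(result: ScreeningResult, k: int) -> list[ScreeningEntry]:
    """First k entries by rank (rank 1 = highest predicted e.e.)."""
    if not (1 <= k <= result.n):
        raise ValueError(f"k must be in [1, {result.n}], got {k}")
    return list(result.entries[:k])


def bin_distribution(
    result: ScreeningResult, thresholds: tuple[float, float] = (0.40, 0.80)
) -> tuple[int, ...]:
    """Counts of candidates per predicted-e.e. interval.

    With the default cut points (0.40, 0.80): ee < 0.40, 0.40 ≤ ee ≤ 0.80,
    ee > 0.80 — boundaries inclusive in the middle bin.  Counts always sum
    to the library size.
    """
    ts = tuple(thresholds)
    if list(ts) != sorted(ts) or len(set(ts)) != len(ts):
        raise ValueError("thresholds must be strictly increasing")
    if any(not (0.0 < t < 1.0) for t in ts):
        raise ValueError("thresholds must lie in (0, 1)")
    ee = np.array([e.ee_pred for e in result.entries])
    counts = [int(np.sum(ee < ts[0]))]
    for i, (lo, hi) in enumerate(zip(ts[:-1], ts[1:])):
        if i == 0:  # first interior bin closed on both ends ("between lo and hi")
            counts.append(int(np.sum((ee >= lo) & (ee <= hi))))
        else:  # later interior bins half-open so boundaries are never double-counted
            counts.append(int(np.sum((ee > lo) & (ee <= hi))))
    counts.append(int(np.sum(ee > ts[-1])))
    return tuple(counts)
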