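"""Synthetic reaction datasets with a known latent SPR and domain shift.

The generator emulates the statistical shape of a small asymmetric-catalysis
screening campaign:

* descriptor tables for a pool of 11 indoles × 14 alkenes × 25 CCAs with the
  default 35/6/66 block widths, drawn from a low-rank factor model (strongly
  collinear columns over a few latent structural factors, one heavy-tailed)
  to mimic the collinearity of real physical-organic descriptor tables;
* a **source domain** of 59 records whose true ΔΔG is a sparse linear
  function of the encoding, rescaled so realised selectivities span roughly
  0–2.2 kcal/mol (≈ 0–95 % e.e. at 298 K), plus Gaussian measurement noise;
* a **target domain** of 10 records sharing one fixed (indole, alkene)
  context, whose true ΔΔG is the source SPR *plus* a structured,
  CCA-dependent perturbation g of ~0.3 kcal/mol — the domain shift that delta
  learning must capture;
* a combinatorial candidate library (4 backbones × 90 N-substituents = 360
  CCAs) with known true target-domain selectivity for every candidate.

Because the latent weights and the perturbation are known, transfer-learning
benefit is measurable as parameter recovery: :func:`recovery_experiment`
runs the full pipeline end-to-end and reports base-model CV metrics, LOO
correction MAEs, the naive pooled baseline, and the rank each model assigns
to the library's true best candidate.

All randomness flows from ``config.seed`` through named substreams
(tables / latent / source / perturbation / target / library), so each stage
is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .base_model import RegressorSpec, fit_base, kfold_cv, mae
from .delta_transfer import (
    DEFAULT_DELTA_SPEC,
    compute_residuals,
    fit_delta,
    fit_naive_pooled,
    loo_evaluate,
    TransferModel,
)
from .reaction_data import (
    DescriptorTable,
    EncodedDataset,
    ReactionRecord,
    ddg_to_ee,
    encode_dataset,
)
from .virtual_screen import (
    ScreeningContext,
    bin_distribution,
    enumerate_candidates,
    pair_table_source,
    screen,
)

__all__ = [
    "SyntheticSPRConfig",
    "SyntheticLibrary",
    "LatentSPR",
    "Perturbation",
    "generate_descriptor_library",
    "make_latent",
    "make_perturbation",
    "generate_source_domain",
    "generate_target_domain",
    "true_candidate_scores",
    "recovery_experiment",
    "RecoveryReport",
    "write_library",
    "write_records",
]

_SUBSTREAMS = {
    "tables": 1,
    "latent": 2,
    "source": 3,
    "perturbation": 4,
    "target": 5,
    "library": 6,
}

#: Hard cap applied to generated e.e. (records reject ee ≥ 0.999).
_EE_CAP = 0.9985


@dataclass(frozen=True)
class SyntheticSPRConfig:
    """Study conditions for the simulated screening campaign.

    Defaults mirror a realistic small-data campaign: 59 source records drawn
    from an 11 × 14 × 25 entity pool, 10 target CCAs in one fixed substrate
    context, a 0.3 kcal/mol sparse-linear perturbation on the CCA block and
    0.05 kcal/mol measurement noise.
    """

    block_dims: tuple[int, int, int] = (35, 6, 66)
    n_indoles: int = 11
    n_alkenes: int = 14
    n_ccas: int = 25
    n_source_records: int = 59
    n_target_ccas: int = 10
    library_backbones: int = 4
    library_substituents: int = 90
    true_weight_sparsity: float = 0.15
    weight_scale: float = 2.2  # kcal/mol: upper end of realised true ΔΔG
    perturbation_mode: str = "sparse_linear_on_cca"  # none | sparse_linear_on_cca | nonlinear_on_cca
    perturbation_amplitude: float = 0.3  # kcal/mol, mean |g| over the CCA pool
    noise_sd: float = 0.05  # kcal/mol
    temperature: float = 298.15  # kelvin
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_indoles,
            self.n_alkenes,
            self.n_ccas,
            self.n_source_records,
            self.n_target_ccas,
            self.library_backbones,
            self.library_substituents,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0 or self.perturbation_amplitude < 0:
            raise ValueError("noise_sd and perturbation_amplitude must be ≥ 0")
        if self.n_target_ccas > self.n_ccas:
            raise ValueError("n_target_ccas cannot exceed the CCA pool size")
        if self.perturbation_mode not in (
            "none",
            "sparse_linear_on_cca",
            "nonlinear_on_cca",
        ):
            raise ValueError(f"unknown perturbation_mode {self.perturbation_mode!r}")
        if not (0 < self.true_weight_sparsity <= 1):
            raise ValueError("true_weight_sparsity must be in (0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named, seed-derived random substream for one generation stage."""
        return np.random.default_rng([self.seed, _SUBSTREAMS[stream]])


@dataclass(frozen=True)
class SyntheticLibrary:
    """Descriptor tables for the entity pools plus the candidate library."""

    tables: Mapping[str, DescriptorTable]
    candidate_frame: pd.DataFrame  # backbone_id, substituent_id, d00..d65
    backbone_ids: tuple[str, ...]
    substituent_ids: tuple[str, ...]


#: Fraction of a descriptor's variance that is idiosyncratic (not shared
#: through the latent factors); real descriptor tables are strongly collinear.
_IDIO_SD = 0.3


def _factor_rank(width: int) -> int:
    """Latent dimensionality per entity class: ~1 factor per 12 descriptors.

    Physical-organic descriptor tables are massively redundant — e.g. dozens
    of steric and charge columns for a catalyst family that varies in a
    single substituent reflect only a handful of structural degrees of
    freedom (a Sterimol-type steric triplet plus electronics).
    """
    return max(2, int(np.ceil(width / 12)))


def _draw_loadings(rng: np.random.Generator, width: int, rank: int) -> np.ndarray:
    return rng.standard_normal((width, rank)) / np.sqrt(rank)


def _draw_factors(rng: np.random.Generator, n: int, rank: int) -> np.ndarray:
    """Latent factors: standard normal, first factor heavy-tailed (t₃)."""
    F = rng.standard_normal((n, rank))
    F[:, 0] = rng.standard_t(3, size=n) / np.sqrt(3.0)
    return F


def _descriptors_from_factors(
    rng: np.random.Generator, factors: np.ndarray, loadings: np.ndarray
) -> np.ndarray:
    """Collinear descriptor block: factors × loadings + idiosyncratic noise.

    Mimics quantum-chemically derived descriptor tables, where dozens of
    steric/electronic columns reflect a handful of underlying structural
    degrees of freedom.
    """
    n, width = factors.shape[0], loadings.shape[0]
    return factors @ loadings.T + _IDIO_SD * rng.standard_normal((n, width))


def generate_descriptor_library(config: SyntheticSPRConfig) -> SyntheticLibrary:
    """Draw descriptor tables for all entity classes and the candidate library.

    Each class's descriptors follow a low-rank factor model (collinear
    columns over a handful of latent structural factors).  Candidate CCA
    vectors reuse the *same* CCA loading matrix with latent factors composed
    as backbone contribution + substituent contribution (each variance ½), so
    the library lives in the same descriptor space as the source-pool CCAs
    while keeping combinatorial structure.
    """
    rng = config.rng("tables")
    d_ind, d_alk, d_cca = config.block_dims
    tables = {}
    loadings = {}
    for cls, n, width, prefix in (
        ("indole", config.n_indoles, d_ind, "I"),
        ("alkene", config.n_alkenes, d_alk, "A"),
        ("cca", config.n_ccas, d_cca, "C"),
    ):
        rank = _factor_rank(width)
        L = _draw_loadings(rng, width, rank)
        loadings[cls] = L
        F = _draw_factors(rng, n, rank)
        ids = [f"{prefix}{i + 1:02d}" for i in range(n)]
        frame = pd.DataFrame(
            _descriptors_from_factors(rng, F, L),
            index=pd.Index(ids, name="entity_id"),
            columns=[f"{cls[:3]}_d{j:02d}" for j in range(width)],
        )
        tables[cls] = DescriptorTable(entity_class=cls, frame=frame)

    lib_rng = config.rng("library")
    backbone_ids = tuple(f"B{i + 1}" for i in range(config.library_backbones))
    substituent_ids = tuple(f"S{i + 1:02d}" for i in range(config.library_substituents))
    rank = _factor_rank(d_cca)
    b_fac = _draw_factors(lib_rng, config.library_backbones, rank) * np.sqrt(0.5)
    s_fac = _draw_factors(lib_rng, config.library_substituents, rank) * np.sqrt(0.5)
    rows = []
    for bi, b in enumerate(backbone_ids):
        for si, s in enumerate(substituent_ids):
            vec = _descriptors_from_factors(
                lib_rng, (b_fac[bi] + s_fac[si])[None, :], loadings["cca"]
            )[0]
            rows.append(
                {
                    "backbone_id": b,
                    "substituent_id": s,
                    **{f"cca_d{j:02d}": vec[j] for j in range(d_cca)},
                }
            )
    return SyntheticLibrary(
        tables=tables,
        candidate_frame=pd.DataFrame(rows),
        backbone_ids=backbone_ids,
        substituent_ids=substituent_ids,
    )


@dataclass(frozen=True)
class LatentSPR:
    """The generator's ground truth: ΔΔG_true(x) = w·x + b (kcal/mol)."""

    weights: np.ndarray  # full encoding length (temperature weight = 0)
    intercept: float

    def ddg(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.intercept


def _entity_contributions(lib: SyntheticLibrary, w_blocks):
    w_ind, w_alk, w_cca = w_blocks
    zi = lib.tables["indole"].frame.to_numpy() @ w_ind
    za = lib.tables["alkene"].frame.to_numpy() @ w_alk
    zc = lib.tables["cca"].frame.to_numpy() @ w_cca
    return zi, za, zc


def make_latent(config: SyntheticSPRConfig, lib: SyntheticLibrary) -> LatentSPR:
    """Draw sparse latent weights and rescale to the configured dynamic range.

    A fraction ``true_weight_sparsity`` of the descriptor dimensions (never
    temperature) get standard-normal weights; the affine map is then scaled so
    true ΔΔG over the *full* combination pool spans [0.05, weight_scale].
    """
    rng = config.rng("latent")
    d_ind, d_alk, d_cca = config.block_dims
    p = d_ind + d_alk + d_cca
    n_active = max(3, int(round(config.true_weight_sparsity * p)))
    active = rng.choice(p, size=min(n_active, p), replace=False)
    w = np.zeros(p)
    w[active] = rng.standard_normal(active.size)
    w_blocks = (w[:d_ind], w[d_ind : d_ind + d_alk], w[d_ind + d_alk :])
    zi, za, zc = _entity_contributions(lib, w_blocks)
    pool = zi[:, None, None] + za[None, :, None] + zc[None, None, :]
    lo, hi = float(pool.min()), float(pool.max())
    span = hi - lo if hi > lo else 1.0
    a = (config.weight_scale - 0.05) / span
    b = 0.05 - a * lo
    weights_full = np.concatenate([a * w, [0.0]])  # temperature carries no signal
    return LatentSPR(weights=weights_full, intercept=b)


@dataclass(frozen=True)
class Perturbation:
    """The domain shift g acting on the CCA descriptor block (kcal/mol).

    ``g(cca_block_matrix)`` returns one value per CCA.  The scale is
    calibrated so mean |g| over the source CCA pool equals the configured
    amplitude.
    """

    mode: str
    columns: np.ndarray  # indices into the CCA block
    weights: np.ndarray
    scale: float

    def g(self, cca_block: np.ndarray) -> np.ndarray:
        cca_block = np.atleast_2d(np.asarray(cca_block, dtype=float))
        if self.mode == "none":
            return np.zeros(cca_block.shape[0])
        proj = cca_block[:, self.columns] @ self.weights
        if self.mode == "sparse_linear_on_cca":
            return self.scale * proj
        return self.scale * np.tanh(proj)  # nonlinear_on_cca: ridge function


def make_perturbation(config: SyntheticSPRConfig, lib: SyntheticLibrary) -> Perturbation:
    """Draw the CCA-block perturbation and calibrate its amplitude."""
    if config.perturbation_mode == "none" or config.perturbation_amplitude == 0:
        return Perturbation(
            mode="none", columns=np.array([], dtype=int), weights=np.array([]), scale=0.0
        )
    rng = config.rng("perturbation")
    d_cca = config.block_dims[2]
    n_cols = 3 if config.perturbation_mode == "sparse_linear_on_cca" else 2
    cols = np.sort(rng.choice(d_cca, size=n_cols, replace=False))
    w = rng.standard_normal(n_cols)
    pool = lib.tables["cca"].frame.to_numpy()[:, cols]
    proj = pool @ w
    raw = proj if config.perturbation_mode == "sparse_linear_on_cca" else np.tanh(proj)
    mean_abs = float(np.mean(np.abs(raw)))
    scale = config.perturbation_amplitude / mean_abs if mean_abs > 0 else 0.0
    return Perturbation(
        mode=config.perturbation_mode, columns=cols, weights=w, scale=scale
    )


def _records_from_ddg(
    ddg_true: np.ndarray,
    noise: np.ndarray,
    ids: Sequence[tuple[str, str, str]],
    domain: str,
    prefix: str,
    temperature: float,
) -> list[ReactionRecord]:
    ddg_obs = ddg_true + noise
    ee = np.clip(ddg_to_ee(ddg_obs, temperature), 0.0, _EE_CAP)
    return [
        ReactionRecord(
            reaction_id=f"{prefix}-{i + 1:03d}",
            domain=domain,
            indole_id=ind,
            alkene_id=alk,
            cca_id=cca,
            temperature=temperature,
            ee_observed=float(ee[i]),
        )
        for i, (ind, alk, cca) in enumerate(ids)
    ]


def generate_source_domain(
    config: SyntheticSPRConfig,
    lib: SyntheticLibrary,
    latent: LatentSPR | None = None,
) -> list[ReactionRecord]:
    """Sample source-reaction records: distinct entity combinations + noise.

    Observed ΔΔG is the latent value plus N(0, noise_sd); the stored e.e. is
    the back-converted value clipped into [0, 0.9985] so every record
    satisfies the e.e. validity contract.
    """
    latent = latent if latent is not None else make_latent(config, lib)
    rng = config.rng("source")
    n_pool = config.n_indoles * config.n_alkenes * config.n_ccas
    if config.n_source_records > n_pool:
        raise ValueError("more source records requested than distinct combinations")
    flat = rng.choice(n_pool, size=config.n_source_records, replace=False)
    combos = np.unravel_index(flat, (config.n_indoles, config.n_alkenes, config.n_ccas))
    ind_ids = lib.tables["indole"].entity_ids
    alk_ids = lib.tables["alkene"].entity_ids
    cca_ids = lib.tables["cca"].entity_ids
    ids = [
        (ind_ids[i], alk_ids[a], cca_ids[c])
        for i, a, c in zip(*(arr.tolist() for arr in combos))
    ]
    X = np.vstack(
        [
            np.concatenate(
                [
                    lib.tables["indole"].vector(ind),
                    lib.tables["alkene"].vector(alk),
                    lib.tables["cca"].vector(cca),
                    [config.temperature],
                ]
            )
            for ind, alk, cca in ids
        ]
    )
    noise = rng.normal(0.0, config.noise_sd, size=len(ids)) if config.noise_sd else np.zeros(len(ids))
    return _records_from_ddg(
        latent.ddg(X), noise, ids, "source", "rxn1", config.temperature
    )


def _target_context(
    config: SyntheticSPRConfig, lib: SyntheticLibrary, latent: LatentSPR
) -> tuple[str, str]:
    """Fixed (indole, alkene) for the target campaign.

    Chosen as the pair whose worst-case CCA selectivity is highest, keeping
    all true target ΔΔG comfortably above zero so the perturbation never
    pushes a measurement through the e.e. sign boundary.
    """
    d_ind, d_alk, _ = config.block_dims
    w = latent.weights
    w_blocks = (w[:d_ind], w[d_ind : d_ind + d_alk], w[d_ind + d_alk : -1])
    zi, za, zc = _entity_contributions(lib, w_blocks)
    floor = zi[:, None] + za[None, :] + zc.min()  # min over CCAs per (i, a)
    i, a = np.unravel_index(int(np.argmax(floor)), floor.shape)
    return lib.tables["indole"].entity_ids[i], lib.tables["alkene"].entity_ids[a]


def generate_target_domain(
    config: SyntheticSPRConfig,
    lib: SyntheticLibrary,
    latent: LatentSPR | None = None,
    perturbation: Perturbation | None = None,
) -> list[ReactionRecord]:
    """Target-reaction records: fixed substrate context, perturbed SPR.

    ΔΔG_true = w·x + g(x_CCA); the same latent weights as the source domain,
    shifted by the CCA-dependent perturbation.
    """
    latent = latent if latent is not None else make_latent(config, lib)
    perturbation = (
        perturbation if perturbation is not None else make_perturbation(config, lib)
    )
    rng = config.rng("target")
    ind_id, alk_id = _target_context(config, lib, latent)
    cca_ids = lib.tables["cca"].entity_ids
    chosen = rng.choice(config.n_ccas, size=config.n_target_ccas, replace=False)
    ids = [(ind_id, alk_id, cca_ids[c]) for c in sorted(chosen.tolist())]
    cca_block = np.vstack([lib.tables["cca"].vector(c) for _, _, c in ids])
    X = np.vstack(
        [
            np.concatenate(
                [
                    lib.tables["indole"].vector(ind),
                    lib.tables["alkene"].vector(alk),
                    cca_block[i],
                    [config.temperature],
                ]
            )
            for i, (ind, alk, _) in enumerate(ids)
        ]
    )
    ddg_true = latent.ddg(X) + perturbation.g(cca_block)
    noise = (
        rng.normal(0.0, config.noise_sd, size=len(ids))
        if config.noise_sd
        else np.zeros(len(ids))
    )
    return _records_from_ddg(ddg_true, noise, ids, "target", "rxn2", config.temperature)


def true_candidate_scores(
    config: SyntheticSPRConfig,
    lib: SyntheticLibrary,
    latent: LatentSPR,
    perturbation: Perturbation,
    context: ScreeningContext,
) -> pd.Series:
    """True target-domain ΔΔG for every library candidate (index candidate_id)."""
    d_cca = config.block_dims[2]
    desc_cols = [f"cca_d{j:02d}" for j in range(d_cca)]
    cand = lib.candidate_frame
    cca_block = cand[desc_cols].to_numpy()
    n = len(cand)
    X = np.hstack(
        [
            np.tile(lib.tables["indole"].vector(context.indole_id), (n, 1)),
            np.tile(lib.tables["alkene"].vector(context.alkene_id), (n, 1)),
            cca_block,
            np.full((n, 1), context.temperature),
        ]
    )
    scores = latent.ddg(X) + perturbation.g(cca_block)
    ids = cand["backbone_id"].astype(str) + "|" + cand["substituent_id"].astype(str)
    return pd.Series(scores, index=ids.to_numpy(), name="ddg_true")


DEFAULT_BASE_SPEC = RegressorSpec("linear_svr")


@dataclass(frozen=True)
class RecoveryReport:
    """End-to-end pipeline metrics on one synthetic campaign."""

    base_cv_pearson_r: float | None
    base_cv_mae: float
    loo_mae_uncorrected: float
    loo_mae_corrected: float
    target_mae_naive_loo: float | None
    true_best_candidate_id: str | None
    rank_true_best_transfer: int | None
    rank_true_best_naive: int | None
    rank_true_best_base: int | None
    bin_counts_transfer: tuple[int, ...] | None
    n_candidates: int | None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def recovery_experiment(
    config: SyntheticSPRConfig,
    base_spec: RegressorSpec = DEFAULT_BASE_SPEC,
    delta_spec: RegressorSpec = DEFAULT_DELTA_SPEC,
    k: int = 10,
    include_screen: bool = True,
    include_naive: bool = True,
) -> RecoveryReport:
    """Run the full pipeline on generated data and score it against the truth.

    Steps: generate library + latent + perturbation → fit and cross-validate
    the base model on the source domain → residuals, LOO evaluation and delta
    fit on the target domain → naive pooled baseline (leave-one-out over the
    target points) → screen the candidate library with each model and locate
    the true best candidate's rank.
    """
    lib = generate_descriptor_library(config)
    latent = make_latent(config, lib)
    perturbation = make_perturbation(config, lib)
    source = generate_source_domain(config, lib, latent)
    target = generate_target_domain(config, lib, latent, perturbation)

    src_ds = encode_dataset(source, lib.tables)
    cv = kfold_cv(src_ds, base_spec, k=min(k, src_ds.n), seed=config.seed)
    base = fit_base(src_ds, base_spec, seed=config.seed)

    residuals = compute_residuals(base, target, lib.tables)
    loo = loo_evaluate(residuals, spec=delta_spec, seed=config.seed)
    delta = fit_delta(residuals, spec=delta_spec, seed=config.seed)
    transfer = TransferModel(base=base, delta=delta)

    tgt_ds = encode_dataset(target, lib.tables)

    naive_mae = None
    naive_full = None
    if include_naive:
        preds = np.empty(tgt_ds.n)
        for i in range(tgt_ds.n):
            keep = [j for j in range(tgt_ds.n) if j != i]
            part = EncodedDataset(
                X=tgt_ds.X[keep],
                y=tgt_ds.y[keep],
                reaction_ids=tuple(tgt_ds.reaction_ids[j] for j in keep),
                column_names=tgt_ds.column_names,
            )
            model_i = fit_naive_pooled(src_ds, part, base_spec, seed=config.seed)
            preds[i] = model_i.predict_matrix(tgt_ds.X[i : i + 1])[0]
        naive_mae = mae(preds, tgt_ds.y)
        naive_full = fit_naive_pooled(src_ds, tgt_ds, base_spec, seed=config.seed)

    best_id = rank_transfer = rank_naive = rank_base = None
    bins = None
    n_cand = None
    if include_screen:
        context = ScreeningContext(
            indole_id=target[0].indole_id,
            alkene_id=target[0].alkene_id,
            temperature=config.temperature,
        )
        candidates = enumerate_candidates(
            lib.backbone_ids,
            lib.substituent_ids,
            pair_table_source(lib.candidate_frame),
        )
        truth = true_candidate_scores(config, lib, latent, perturbation, context)
        best_id = str(truth.idxmax())

        def rank_of(model) -> int:
            result = screen(model, candidates, context, lib.tables)
            if model is transfer:
                nonlocal bins, n_cand
                bins = bin_distribution(result)
                n_cand = result.n
            for e in result.entries:
                if e.candidate_id == best_id:
                    return e.rank
            raise AssertionError("true best candidate missing from screen")

        rank_transfer = rank_of(transfer)
        rank_base = rank_of(base)
        if naive_full is not None:
            rank_naive = rank_of(naive_full)

    return RecoveryReport(
        base_cv_pearson_r=cv.pearson_r,
        base_cv_mae=cv.mae,
        loo_mae_uncorrected=loo.mae_uncorrected,
        loo_mae_corrected=loo.mae_corrected,
        target_mae_naive_loo=naive_mae,
        true_best_candidate_id=best_id,
        rank_true_best_transfer=rank_transfer,
        rank_true_best_naive=rank_naive,
        rank_true_best_base=rank_base,
        bin_counts_transfer=bins,
        n_candidates=n_cand,
    )


# ---------------------------------------------------------------------------
# CSV round-trip helpers (same schemas consumed by reaction_data loaders)


def write_library(lib: SyntheticLibrary, outdir) -> dict[str, Path]:
    """Write descriptor tables + candidate library as CSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for cls, table in lib.tables.items():
        p = outdir / f"{cls}_descriptors.csv"
        table.frame.to_csv(p)
        paths[cls] = p
    p = outdir / "candidate_library.csv"
    lib.candidate_frame.to_csv(p, index=False)
    paths["candidates"] = p
    return paths


def write_records(records: Sequence[ReactionRecord], path) -> Path:
    """Write reaction records in the loader's CSV schema."""
    path = Path(path)
    pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id,
                "indole_id": r.indole_id,
                "alkene_id": r.alkene_id,
                "cca_id": r.cca_id,
                "temperature_k": r.temperature,
                "ee": r.ee_observed,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
    return path
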