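"""End-to-end pipeline: validate → train → transfer → screen, with reports.

A :class:`RunConfig` (typically loaded from YAML) names the input tables and
record files, the regressor specifications, seeds and output directory.
:func:`run_pipeline` executes the stages in order, writes the fitted models,
the LOO report and the ranked screening CSV, and returns a JSON-able run
summary carrying every metric plus the config hash and seed — so two runs
with the same config are byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .base_model import RegressorSpec, fit_base, kfold_cv, save_model
from .delta_transfer import (
    DEFAULT_DELTA_SPEC,
    TransferModel,
    compute_residuals,
    fit_delta,
    loo_evaluate,
    save_transfer,
)
from .reaction_data import (
    encode_dataset,
    load_descriptor_table,
    load_reaction_records,
    validate_dataset,
)
from .virtual_screen import (
    ScreeningContext,
    bin_distribution,
    enumerate_candidates,
    pair_table_source,
    screen,
    top_k,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for actionable messages."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run.

    Paths are resolved relative to the YAML file's directory when loaded via
    :meth:`from_yaml`.  Unknown keys are rejected.
    """

    indole_csv: str
    alkene_csv: str
    cca_csv: str
    source_records_csv: str
    target_records_csv: str
    candidate_library_csv: str
    context_indole_id: str
    context_alkene_id: str
    context_temperature_k: float
    outdir: str
    base_algorithm: str = "linear_svr"
    base_hyperparameters: dict = field(default_factory=dict)
    delta_algorithm: str = DEFAULT_DELTA_SPEC.algorithm
    delta_hyperparameters: dict = field(
        default_factory=lambda: dict(DEFAULT_DELTA_SPEC.hyperparameters)
    )
    k_folds: int = 10
    seed: int = 0
    ee_thresholds: tuple[float, float] = (0.40, 0.80)
    top_k: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        missing = {
            f.name
            for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING
            and f.default_factory is dataclasses.MISSING
        } - set(raw)
        if missing:
            raise ValueError(f"{path}: missing required keys {sorted(missing)}")
        base = path.parent
        for key in (
            "indole_csv",
            "alkene_csv",
            "cca_csv",
            "source_records_csv",
            "target_records_csv",
            "candidate_library_csv",
            "outdir",
        ):
            raw[key] = str((base / raw[key]).resolve())
        if "ee_thresholds" in raw:
            raw["ee_thresholds"] = tuple(raw["ee_thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {
        "chirtransfer_version": __version__,
        "python": platform.python_version(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute validate → train → transfer → screen and write all artifacts.

    Returns the run summary (also written to ``outdir/run_summary.json``).
    Raises :class:`PipelineError` naming the failing stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)

    # -- validate ----------------------------------------------------------
    try:
        tables = {
            "indole": load_descriptor_table(config.indole_csv, "indole"),
            "alkene": load_descriptor_table(config.alkene_csv, "alkene"),
            "cca": load_descriptor_table(config.cca_csv, "cca"),
        }
        source = load_reaction_records(config.source_records_csv, domain="source")
        target = load_reaction_records(config.target_records_csv, domain="target")
        report = validate_dataset(source + target, tables)
        (outdir / "validation_report.json").write_text(report.to_json())
        if not report.ok:
            raise ValueError(
                f"{len(report.issues)} validation issue(s); "
                f"see {outdir / 'validation_report.json'}"
            )
        if config.context_indole_id not in tables["indole"]:
            raise ValueError(f"context indole {config.context_indole_id!r} unknown")
        if config.context_alkene_id not in tables["alkene"]:
            raise ValueError(f"context alkene {config.context_alkene_id!r} unknown")
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError("validate", str(exc)) from exc

    # -- train -------------------------------------------------------------
    try:
        base_spec = RegressorSpec(config.base_algorithm, config.base_hyperparameters)
        src_ds = encode_dataset(source, tables)
        cv = kfold_cv(src_ds, base_spec, k=config.k_folds, seed=config.seed)
        base = fit_base(src_ds, base_spec, seed=config.seed)
        save_model(base, outdir / "base_model.json")
    except (ValueError, KeyError) as exc:
        raise PipelineError("train", str(exc)) from exc

    # -- transfer ----------------------------------------------------------
    try:
        delta_spec = RegressorSpec(config.delta_algorithm, config.delta_hyperparameters)
        residuals = compute_residuals(base, target, tables)
        loo = loo_evaluate(residuals, spec=delta_spec, seed=config.seed)
        delta = fit_delta(residuals, spec=delta_spec, seed=config.seed)
        transfer = TransferModel(base=base, delta=delta)
        save_transfer(transfer, outdir / "transfer_model.json")
        loo_payload = {
            **prov,
            "n": loo.n,
            "mae_uncorrected_kcal_mol": loo.mae_uncorrected,
            "mae_corrected_kcal_mol": loo.mae_corrected,
            "per_point": {
                k: {"ddg_pred_corrected": v[0], "ddg_exp": v[1]}
                for k, v in loo.per_point.items()
            },
        }
        (outdir / "loo_report.json").write_text(json.dumps(loo_payload, indent=2))
    except (ValueError, KeyError) as exc:
        raise PipelineError("transfer", str(exc)) from exc

    # -- screen ------------------------------------------------------------
    try:
        lib_frame = pd.read_csv(config.candidate_library_csv)
        backbones = list(dict.fromkeys(lib_frame["backbone_id"].astype(str)))
        substituents = list(dict.fromkeys(lib_frame["substituent_id"].astype(str)))
        candidates = enumerate_candidates(
            backbones, substituents, pair_table_source(lib_frame)
        )
        context = ScreeningContext(
            indole_id=config.context_indole_id,
            alkene_id=config.context_alkene_id,
            temperature=config.context_temperature_k,
        )
        result = screen(transfer, candidates, context, tables)
        frame = result.to_frame()
        frame.insert(0, "config_hash", prov["config_hash"])
        frame.insert(1, "seed", prov["seed"])
        frame.to_csv(outdir / "screen.csv", index=False)
        bins = bin_distribution(result, config.ee_thresholds)
        best = top_k(result, min(config.top_k, result.n))
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError("screen", str(exc)) from exc

    summary = {
        **prov,
        "stages": ["validate", "train", "transfer", "screen"],
        "n_source": len(source),
        "n_target": len(target),
        "base_cv": {
            "k": cv.k,
            "pearson_r": cv.pearson_r,
            "mae_kcal_mol": cv.mae,
        },
        "loo": {
            "n": loo.n,
            "mae_uncorrected_kcal_mol": loo.mae_uncorrected,
            "mae_corrected_kcal_mol": loo.mae_corrected,
        },
        "screen": {
            "n_candidates": result.n,
            "ee_thresholds": list(config.ee_thresholds),
            "bin_counts": list(bins),
            "top_k": [
                {
                    "candidate_id": e.candidate_id,
                    "ddg_pred_kcal_mol": e.ddg_pred,
                    "ee_pred": e.ee_pred,
                    "rank": e.rank,
                }
                for e in best
            ],
        },
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
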