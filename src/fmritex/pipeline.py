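"""End-to-end orchestration: extract -> label -> stats -> fit -> evaluate.

Every stage is an importable function; ``run_pipeline`` chains them and
writes self-describing artifacts (feature table, group-comparison table,
correlation matrix, stepwise model, cross-validation results) plus a run
manifest recording config, seed and package version. Reruns with the same
config and seed reproduce all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from fmritex.errors import FmritexError
from fmritex.evaluation import EvalResult, make_splits, run_cv
from fmritex.stepwise import StepwiseModel, model_table, stepwise_select
from fmritex.synthetic import (
    CORRELATED_BLOCK,
    ImageGenConfig,
    VolumeDataset,
    generate_volume_dataset,
)
from fmritex.texture import extract_feature_table
from fmritex.univariate import feature_correlations, group_comparison_table
from fmritex.volumes import read_manifest, read_mask, read_volume

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Settings for a full run; defaults mirror the study's analysis."""

    manifest: str | None = None      # ROI manifest CSV, or None to simulate
    n_levels: int = 8
    distance: int = 1
    p_enter: float = 0.05
    p_remove: float = 0.15
    n_train: int = 12
    n_repeats: int = 100
    seed: int = 0
    out_dir: str = "fmritex_run"


class StageError(FmritexError):
    """Wraps a stage failure with stage and ROI context."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


def extract_stage(config: RunConfig) -> pd.DataFrame:
    """Feature table from a manifest of NIfTI volumes/masks, or simulated."""
    try:
        if config.manifest is None:
            dataset = generate_volume_dataset(
                ImageGenConfig(seed=config.seed))
            volumes, rois = dataset.volumes, dataset.rois
        else:
            df = read_manifest(config.manifest)
            volumes = {}
            rois = []
            root = Path(config.manifest).parent
            for row in df.itertuples():
                path = Path(row.mask_path)
                if not path.is_absolute():
                    path = root / path
                rois.append(read_mask(path, row.subject_id, row.roi_id,
                                      row.label))
            for sid in df["subject_id"].unique():
                vol_path = root / f"{sid}_mean_epi.nii"
                volumes[sid] = read_volume(vol_path)
        return extract_feature_table(volumes, rois, n_levels=config.n_levels,
                                     distance=config.distance)
    except FmritexError as exc:
        raise StageError("extract", str(exc)) from exc
    except FileNotFoundError as exc:
        raise StageError("extract", f"missing input file: {exc}") from exc


def stats_stage(table: pd.DataFrame, out: Path) -> pd.DataFrame:
    comparison = group_comparison_table(table)
    comparison.to_csv(out / "group_comparison.csv", index=False)
    corr = feature_correlations(table, CORRELATED_BLOCK)
    corr.to_csv(out / "feature_correlations.csv")
    return comparison

def fit_stage(table: pd.DataFrame, config: RunConfig,
              out: Path) -> StepwiseModel:
    model = stepwise_select(table, p_enter=config.p_enter,
                            p_remove=config.p_remove)
    model.to_json(out / "stepwise_model.json")
    model_table(model).to_csv(out / "model_table.csv", index=False)
    return model


def evaluate_stage(table: pd.DataFrame, config: RunConfig,
                   out: Path) -> EvalResult:
    plans = make_splits(table["subject_id"], n_train=config.n_train,
                        n_repeats=config.n_repeats, seed=config.seed)
    result = run_cv(table, plans, p_enter=config.p_enter,
                    p_remove=config.p_remove)
    result.to_json(out / "eval_result.json")
    result.per_repeat.to_csv(out / "eval_per_repeat.csv", index=False)
    return result


@dataclasses.dataclass
class RunArtifacts:
    feature_table: pd.DataFrame
    comparison: pd.DataFrame
    model: StepwiseModel
    eval_result: EvalResult
    out_dir: Path


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Run every stage and write artifacts + run manifest to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("extracting texture features")
    table = extract_stage(config)
    table.to_csv(out / "feature_table.csv", index=False)
    logger.info("univariate statistics")
    comparison = stats_stage(table, out)
    logger.info("stepwise model fit")
    model = fit_stage(table, config, out)
    logger.info("grouped cross-validation (%d repeats)", config.n_repeats)
    eval_result = evaluate_stage(table, config, out)

    from fmritex import __version__
    manifest = {"config": dataclasses.asdict(config),
                "version": __version__,
                "n_rois": int(len(table)),
                "selected_features": model.selected_features,
                "aggregate_metrics": eval_result.aggregate}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunArtifacts(feature_table=table, comparison=comparison,
                        model=model, eval_result=eval_result, out_dir=out)
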