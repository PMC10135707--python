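"""The two-stage study pipeline and its run configuration.

Stage I compares perioperative outcomes between difficult and non-difficult
groups (feasibility of the grading itself); stage II trains the image +
clinical classifier with 4-fold cross-validation, merges the fold models by
score averaging, evaluates on a held-out test set, and produces
registration-averaged GradCAM++ attention maps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cam as cam_mod
from .cohort_stats import (
    ContingencyTable2x2,
    TestResult,
    mann_whitney,
    pearson_chi2_2x2,
    t_test_from_summary,
)
from .errors import ConfigurationError
from .metrics import MetricReport, aggregate_folds, compute_metrics, confusion
from .model import NetworkConfig, desk_config
from .phantom import Cohort, CohortConfig, generate_cohort, inlet_band_mask
from .preprocess import pad_to_shape
from .training import (
    MergedModel,
    OptimizerSettings,
    desk_optimizer_settings,
    evaluate_model,
    make_splits,
    train_fold,
)

__all__ = [
    "RunConfig",
    "run_stage1",
    "run_stage2",
    "simulate_outcomes",
    "Stage2Result",
]


@dataclass(frozen=True)
class RunConfig:
    """Complete settings for an end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    network: NetworkConfig = field(default_factory=desk_config)
    optimizer: OptimizerSettings = field(default_factory=desk_optimizer_settings)
    k_folds: int = 4
    test_size: float = 0.25
    cam_layer: str = "layer3"
    cam_top_fraction: float = 0.005
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        from .phantom import LogisticCoefficients, PhantomSpec

        cohort_raw = dict(raw.get("cohort", {}))
        if "coefficients" in cohort_raw:
            cohort_raw["coefficients"] = LogisticCoefficients(**cohort_raw["coefficients"])
        if "phantom" in cohort_raw:
            ph = dict(cohort_raw["phantom"])
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            cohort_raw["phantom"] = PhantomSpec(**ph)
        net_raw = dict(raw.get("network", {}))
        for key in ("input_shape", "stage_block_counts", "stage_channel_widths"):
            if key in net_raw:
                net_raw[key] = tuple(net_raw[key])
        return cls(
            cohort=CohortConfig(**cohort_raw),
            network=NetworkConfig(**net_raw),
            optimizer=OptimizerSettings(**raw.get("optimizer", {})),
            k_folds=raw.get("k_folds", 4),
            test_size=raw.get("test_size", 0.25),
            cam_layer=raw.get("cam_layer", "layer3"),
            cam_top_fraction=raw.get("cam_top_fraction", 0.005),
            seed=raw.get("seed", 0),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ----------------------------------------------------------------------
# Stage I
# ----------------------------------------------------------------------

def simulate_outcomes(manifest: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Synthetic perioperative outcomes with difficulty-linked shifts.

    Difficult cases get longer operations, more blood loss, more diverting
    stomas and more anastomotic leaks; a small random subset has no
    anastomosis and is flagged for exclusion from the comparison.
    """
    # keyed stream: never collides with the cohort generator's stream for the
    # same integer seed (the label mechanism and outcome noise must be
    # independent draws)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    n = len(manifest)
    label = manifest["label"].to_numpy()
    duration = rng.normal(118 + 26 * label, 22, size=n).clip(40, 400)
    blood = np.exp(rng.normal(np.log(20) + 0.45 * label, 0.6, size=n)).clip(5, 600)
    stoma = (rng.random(n) < 0.66 + 0.22 * label).astype(int)
    leak = (rng.random(n) < 0.04 + 0.12 * label).astype(int)
    no_anastomosis = (rng.random(n) < 6 / 108).astype(int)
    return pd.DataFrame(
        {
            "case_id": manifest["case_id"].to_numpy(),
            "duration_min": duration,
            "blood_loss_ml": blood,
            "diverting_stoma": stoma,
            "anastomotic_leak": leak,
            "no_anastomosis": no_anastomosis,
        }
    )


DEFAULT_OUTCOME_TYPES = {
    "duration_min": "continuous_skewed",
    "blood_loss_ml": "continuous_skewed",
    "diverting_stoma": "categorical",
    "anastomotic_leak": "categorical",
    "bmi": "continuous_normal",
    "male": "categorical",
    "neoadjuvant": "categorical",
}


def run_stage1(
    manifest: pd.DataFrame,
    outcomes: pd.DataFrame,
    column_types: Optional[dict[str, str]] = None,
    exclude_col: str | None = "no_anastomosis",
) -> pd.DataFrame:
    """Group-comparison report: one row per variable with summaries and p-value.

    ``column_types`` maps each analyzed column to ``continuous_normal``
    (pooled t-test), ``continuous_skewed`` (Mann-Whitney) or ``categorical``
    (Pearson chi-squared).  Cases flagged in ``exclude_col`` (procedures
    without an anastomosis) are removed first.
    """
    df = manifest.merge(outcomes, on="case_id")
    if exclude_col and exclude_col in df.columns:
        df = df[df[exclude_col] == 0]
    groups = {g: df[df["label"] == g] for g in (1, 0)}
    if any(len(g) == 0 for g in groups.values()):
        raise ConfigurationError("a group is empty after exclusions")
    types = column_types or DEFAULT_OUTCOME_TYPES
    rows = []
    for col, kind in types.items():
        if col not in df.columns:
            continue
        a = groups[1][col].to_numpy(dtype=float)
        b = groups[0][col].to_numpy(dtype=float)
        if kind == "continuous_normal":
            res = t_test_from_summary(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
            summ = (f"{a.mean():.1f} ({a.std(ddof=1):.1f})", f"{b.mean():.1f} ({b.std(ddof=1):.1f})")
            test = "t"
        elif kind == "continuous_skewed":
            res = mann_whitney(a, b)
            summ = (f"{np.median(a):.1f}", f"{np.median(b):.1f}")
            test = "mann-whitney"
        elif kind == "categorical":
            tab = ContingencyTable2x2(
                a=int(a.sum()), b=int(len(a) - a.sum()), c=int(b.sum()), d=int(len(b) - b.sum())
            )
            summ = (f"{int(a.sum())} ({100 * a.mean():.1f})", f"{int(b.sum())} ({100 * b.mean():.1f})")
            try:
                res = pearson_chi2_2x2(tab)
                test = "chi2"
            except ConfigurationError:
                # no events (or all events) in both groups: untestable, not fatal
                res = TestResult(statistic=float("nan"), p_value=float("nan"))
                test = "chi2 (degenerate)"
        else:
            raise ConfigurationError(f"untyped or unknown column type {kind!r} for {col!r}")
        rows.append(
            {
                "variable": col,
                "difficult": summ[0],
                "non_difficult": summ[1],
                "test": test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_difficult": len(a),
                "n_non_difficult": len(b),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Stage II
# ----------------------------------------------------------------------

@dataclass
class Stage2Result:
    cohort: Cohort
    merged: MergedModel
    fold_validation_reports: list[MetricReport]
    fold_test_reports: list[MetricReport]
    merged_report: MetricReport
    merged_confusion: dict
    history: pd.DataFrame
    mean_skeleton: np.ndarray | None
    mean_heatmap: np.ndarray | None
    highlight: np.ndarray | None
    inlet_band_fraction: float | None
    manifest: dict


def run_stage2(config: RunConfig, outdir=None, compute_cam: bool = True) -> Stage2Result:
    """End-to-end stage II: cohort -> preprocess -> 4-fold training -> merge ->
    held-out evaluation -> registration-averaged attention map."""
    rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(dataclasses.replace(config.cohort, seed=int(rng.integers(0, 2**31 - 1))))

    # preprocessing: phantoms are generated at 1.5 mm; center-pad to the input grid
    shape = tuple(config.network.input_shape)
    for case in cohort.cases:
        case.volume = pad_to_shape(case.volume, shape)

    cases_by_id = {c.case_id: c for c in cohort.cases}
    splits = make_splits(cohort.manifest, k=config.k_folds, test_size=config.test_size,
                         seed=int(rng.integers(0, 2**31 - 1)))
    test_cases = [cases_by_id[i] for i in splits[0].test_ids]
    test_labels = np.array([c.label for c in test_cases])

    models, bounds_list, histories = [], [], []
    fold_val_reports, fold_test_reports = [], []
    for split in splits:
        model, bounds, history = train_fold(
            cases_by_id, split, config.network, config.optimizer, seed=int(rng.integers(0, 2**31 - 1))
        )
        models.append(model)
        bounds_list.append(bounds)
        histories.append(history)
        val_cases = [cases_by_id[i] for i in split.validation_ids]
        from .training import _stack  # evaluation stacking helper

        v_vols, v_clin, v_y = _stack(val_cases, bounds)
        fold_val_reports.append(evaluate_model(model.predict_scores(v_vols, v_clin), v_y.astype(int)))
        t_vols, t_clin, t_y = _stack(test_cases, bounds)
        fold_test_reports.append(evaluate_model(model.predict_scores(t_vols, t_clin), t_y.astype(int)))

    merged = MergedModel(models=models, bounds=bounds_list)
    merged_scores = merged.predict(test_cases)
    merged_report = evaluate_model(merged_scores, test_labels)
    preds = (merged_scores >= 0.5).astype(int)
    cm = confusion(preds, test_labels)

    mean_skeleton = mean_heatmap = highlight = None
    band_fraction = None
    if compute_cam:
        volumes = [c.volume for c in test_cases]
        heatmaps = []
        for case in test_cases:
            per_model = []
            for model, b in zip(models, bounds_list):
                from .preprocess import normalize_clinical

                clin = normalize_clinical(case.covariates, b)
                per_model.append(
                    cam_mod.case_heatmap(model, case.volume.astype(np.float32), clin, layer_tag=config.cam_layer)
                )
            heatmaps.append(np.mean(per_model, axis=0))
        ref = cam_mod.pick_reference(volumes)
        mean_skeleton, mean_heatmap = cam_mod.average_heatmap(
            volumes, heatmaps, reference_index=ref, spacing=cohort.cases[0].spacing_mm[0]
        )
        highlight = cam_mod.top_fraction_highlight(mean_heatmap, fraction=config.cam_top_fraction)
        band = inlet_band_mask(volumes[ref], dilate=2)
        band_fraction = float(np.sum(highlight & band) / np.sum(highlight))

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "cohort_meta": cohort.meta,
        "splits": [
            {
                "fold": s.fold_id,
                "train": list(s.train_ids),
                "validation": list(s.validation_ids),
                "test": list(s.test_ids),
            }
            for s in splits
        ],
        "aggregate_validation": dataclasses.asdict(aggregate_folds(fold_val_reports)),
        "aggregate_test": dataclasses.asdict(aggregate_folds(fold_test_reports)),
        "merged_test": dataclasses.asdict(merged_report),
        "merged_confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "inlet_band_fraction": band_fraction,
    }
    result = Stage2Result(
        cohort=cohort,
        merged=merged,
        fold_validation_reports=fold_val_reports,
        fold_test_reports=fold_test_reports,
        merged_report=merged_report,
        merged_confusion=manifest["merged_confusion"],
        history=pd.concat(histories, ignore_index=True),
        mean_skeleton=mean_skeleton,
        mean_heatmap=mean_heatmap,
        highlight=highlight,
        inlet_band_fraction=band_fraction,
        manifest=manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        result.history.to_csv(outdir / "history.csv", index=False)
        for i, model in enumerate(models, start=1):
            model.save(outdir / f"fold{i}.npz")
        if mean_heatmap is not None:
            cam_mod.export_heatmap(mean_heatmap, outdir / "mean_heatmap", spacing=cohort.cases[0].spacing_mm[0])
    return result
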