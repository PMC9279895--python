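"""End-to-end study orchestration: simulate/load -> screen -> nested CV ->
fixed-weight LOOCV -> baselines -> interpretation artifacts.

``run_study`` is deterministic given its configuration: every source of
randomness (simulation, inner-CV splits, baseline initialisation) is derived
from the single master seed in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from .cohort import CohortSpec, MultimodalDataset, generate_cohort, load_dataset
from .evaluation import (
    baseline_harness,
    default_kernel_specs,
    feature_screen,
    loocv_fixed_weights,
    nested_weight_search,
    roc_auc,
    simplex_grid,
)
from .kernels import KernelSpec, KernelWeights, combine_kernels
from .interpretation import contribution_report, kernel_heatmap, kernel_pca, pc_separation

__all__ = ["RunConfig", "run_study"]


@dataclass
class RunConfig:
    """Fully serialisable configuration of one study run."""

    out_dir: str = "results"
    seed: int = 0
    cohort: CohortSpec | None = None        # synthetic source ...
    manifest: str | None = None             # ... or file manifest (exclusive)
    kernels: Mapping[str, KernelSpec] | None = None  # default: linear, z-scored
    grid_step: float = 0.05
    C_options: Sequence[float] = (1.0,)
    inner_folds: int = 5
    run_screen: bool = True
    run_baselines: bool = True
    baseline_methods: Sequence[str] = ("svm_stacked", "random_forest",
                                       "gradient_boosting", "mlp")
    baseline_modalities: Sequence[str] = ("clinical", "eeg", "pet", "all_stacked")
    run_interpretation: bool = True
    figure_format: str = "svg"

    def validate(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ValueError("exactly one of cohort / manifest must be set")
        if self.cohort is not None:
            self.cohort.validate()
        simplex_grid(3, self.grid_step)  # raises on a bad step
        if not self.C_options:
            raise ValueError("C_options must be non-empty")

    def to_jsonable(self) -> dict:
        def conv(obj: Any):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj
        return conv(dataclasses.asdict(self))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in self.to_jsonable().items() if k != "out_dir"}
        text = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("cohort") is not None and not isinstance(d["cohort"], CohortSpec):
            cohort = dict(d["cohort"])
            if "clinical_features" in cohort:
                from .cohort import ClinicalFeature
                cohort["clinical_features"] = tuple(
                    ClinicalFeature(**f) if isinstance(f, Mapping) else ClinicalFeature(*f)
                    for f in cohort["clinical_features"]
                )
            if "eeg_shape" in cohort:
                cohort["eeg_shape"] = tuple(cohort["eeg_shape"])
            d["cohort"] = CohortSpec(**cohort)
        if d.get("kernels") is not None:
            d["kernels"] = {m: (k if isinstance(k, KernelSpec) else KernelSpec(**k))
                            for m, k in d["kernels"].items()}
        return cls(**d)


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def run_study(config: RunConfig) -> dict:
    """Run the full replica and write a result bundle to ``config.out_dir``.

    Stages: dataset (simulated or loaded), group summary, per-feature Welch
    screen, nested weight search, fixed-weight LOOCV at the fold-averaged
    weights, conventional baselines, and kernel interpretation figures.  Any
    stage failure aborts with the stage name; a manifest lists every output
    file together with the config hash.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "config": config.to_jsonable(), "files": []}
    summary: dict = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"].append(name)

    stage = "dataset"
    try:
        if config.cohort is not None:
            dataset = generate_cohort(config.cohort, seed=config.seed)
        else:
            dataset = load_dataset(config.manifest)
        kernel_specs = dict(config.kernels or default_kernel_specs(dataset))

        group = np.where(dataset.y > 0, "case", "control")
        group_summary = {
            m: {
                "case_mean": block[group == "case"].mean().round(4).to_dict(),
                "control_mean": block[group == "control"].mean().round(4).to_dict(),
            }
            for m, block in [("clinical", dataset.blocks["clinical"])]
            if m in dataset.blocks
        }
        emit("group_summary.json", lambda p: _write_json(p, group_summary))

        if config.run_screen:
            stage = "feature_screen"
            screen = feature_screen(dataset)
            emit("feature_screen.csv", lambda p: screen.to_csv(p, index=False))
            summary["screen_significant"] = {
                m: int(screen.loc[screen.modality == m, "significant_bonferroni"].sum())
                for m in dataset.modalities
            }

        stage = "nested_weight_search"
        grid = simplex_grid(len(dataset.modalities), config.grid_step)
        nested = nested_weight_search(
            dataset, kernel_specs, grid=grid, C_options=config.C_options,
            inner_folds=config.inner_folds, seed=config.seed,
        )
        emit("nested_cv.json", lambda p: _write_json(p, nested.to_dict()))
        roc_points, _ = roc_auc(nested.y_true, nested.scores)
        emit("nested_roc.csv", lambda p: roc_points.to_csv(p, index=False))
        contrib = contribution_report(nested)
        emit("kernel_contributions.csv", lambda p: contrib.to_csv(p, index_label="modality"))
        summary["nested"] = nested.metrics
        summary["weights_mean"] = contrib["mean"].round(4).to_dict()
        summary["weights_sd"] = contrib["sd"].round(4).to_dict()

        stage = "fixed_weight_loocv"
        mean_beta = contrib["mean"].to_numpy()
        mean_beta = mean_beta / mean_beta.sum()
        fixed = loocv_fixed_weights(
            dataset, kernel_specs,
            weights=KernelWeights(tuple(mean_beta), dataset.modalities),
            C=float(config.C_options[0]),
        )
        emit("fixed_weights_cv.json", lambda p: _write_json(p, fixed.to_dict()))
        summary["fixed_weights"] = fixed.metrics

        if config.run_baselines:
            stage = "baselines"
            rows = []
            for method in config.baseline_methods:
                for modality in config.baseline_modalities:
                    if modality != "all_stacked" and modality not in dataset.blocks:
                        continue
                    res = baseline_harness(dataset, method=method, modality=modality,
                                           seed=config.seed)
                    rows.append({"method": method, "modality": modality, **res.metrics})
            import pandas as pd
            baselines = pd.DataFrame(rows)
            emit("baselines.csv", lambda p: baselines.to_csv(p, index=False))
            summary["baselines"] = rows

        if config.run_interpretation:
            stage = "interpretation"
            from .evaluation import _modality_kernels
            all_rows = np.arange(dataset.n)
            kernels = _modality_kernels(dataset, kernel_specs, all_rows, all_rows)
            combined = combine_kernels(
                kernels, KernelWeights(tuple(mean_beta), dataset.modalities))
            fmt = config.figure_format
            for k in [*kernels, combined]:
                name = f"kernel_{k.modality}.{fmt}"
                emit(name, lambda p, kk=k: kernel_heatmap(kk, dataset.y, p))
            kpca = kernel_pca(combined, n_components=2)
            emit("kernel_pca_scores.csv",
                 lambda p: kpca.to_frame().to_csv(p, index_label="subject_id"))
            sep = pc_separation(kpca.scores, dataset.y)
            summary["pc_separation"] = {
                "coef": sep.coef.tolist(), "intercept": sep.intercept,
                "in_sample_accuracy": sep.accuracy, "separable": sep.separable,
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    emit("summary.json", lambda p: _write_json(p, summary))
    _write_json(out / "manifest.json", manifest)
    manifest["files"].append("manifest.json")
    return {"summary": summary, "manifest": manifest, "out_dir": str(out)}
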