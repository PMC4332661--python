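"""End-to-end orchestration: config, seed fan-out, figures, results JSON.

A single master seed is fanned out to the pipeline stages through
``numpy.random.SeedSequence(master_seed).spawn(...)`` in a fixed order
(simulation, feature-matrix sampling, experiment-1 split, experiment-1
fit/bootstrap, experiment-2 split, experiment-2 fit/bootstrap), so a rerun
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from cortsep import classify, corrfeat, hpdiv, synthetic
from cortsep.io_atlas import CASE, CONTROL, ThicknessTable, read_thickness_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline constants; every default mirrors the study protocol."""

    case_table_path: str | None = None
    control_table_path: str | None = None
    dialect: str = "plain"
    synthetic: dict = field(default_factory=dict)
    use_synthetic: bool = True
    k_features: int = 15
    g: int = 6
    n_subsets_per_cohort: int = 500
    n_train_rows: int = 700
    n_test_rows: int = 300
    n_train_case_subjects: int = 40
    n_train_control_subjects: int = 24
    cv_folds: int = 5
    n_boot: int = 100
    penalty_grid: list[float] | None = None
    fisher_z: bool = False
    loss: str = "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "k_features": self.k_features,
            "g": self.g,
            "n_subsets_per_cohort": self.n_subsets_per_cohort,
            "n_train_rows": self.n_train_rows,
            "n_test_rows": self.n_test_rows,
            "cv_folds": self.cv_folds,
            "n_boot": self.n_boot,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if 2 * self.n_subsets_per_cohort != self.n_train_rows + self.n_test_rows:
            raise ValueError(
                "inconsistent sizes: 2 * n_subsets_per_cohort must equal "
                f"n_train_rows + n_test_rows ({2 * self.n_subsets_per_cohort} != "
                f"{self.n_train_rows + self.n_test_rows})"
            )
        if not self.use_synthetic and not (self.case_table_path and self.control_table_path):
            raise ValueError("non-synthetic runs need case and control table paths")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0])


def _load_tables(config: PipelineConfig) -> tuple[ThicknessTable, ThicknessTable, dict]:
    if config.use_synthetic:
        spec, hub_pairs = synthetic.hub_scenario(seed=config.seed, **config.synthetic)
        case, control = synthetic.simulate_cohorts(spec, seed=config.seed)
        prov = {
            "source": "synthetic",
            "n_case": spec.n_case,
            "n_control": spec.n_control,
            "planted_hub_pairs": [[p.i, p.j] for p in hub_pairs],
        }
        return case, control, prov
    case = read_thickness_table(config.case_table_path, config.dialect, cohort_label=CASE)
    control = read_thickness_table(config.control_table_path, config.dialect, cohort_label=CONTROL)
    return case, control, {
        "source": "files",
        "case_table_path": config.case_table_path,
        "control_table_path": config.control_table_path,
    }


def _heatmap(ax, matrix, title):
    im = ax.imshow(matrix, vmin=-0.1, vmax=1.0, cmap="jet", interpolation="nearest")
    ax.set_title(title)
    return im


def _plot_correlations(case_corr, control_corr, diff, out: Path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5))
    _heatmap(axes[0], control_corr, "control correlations")
    _heatmap(axes[1], case_corr, "case correlations")
    im = _heatmap(axes[2], diff, "absolute difference")
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(out, dpi=120)
    plt.close(fig)


def _plot_curve(curve: hpdiv.SeparabilityCurve, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.feature_counts, curve.separability_values, "o-")
    ax.set_xlabel("number of features")
    ax.set_ylabel("separability")
    ax.set_ylim(0.45, 1.02)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def _plot_embedding(coords, labels, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, color in ((CONTROL, "tab:blue"), (CASE, "tab:red")):
        mask = np.asarray(labels) == lab
        ax.scatter(coords[mask, 0], coords[mask, 1], s=8, alpha=0.6, label=lab, color=color)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def _plot_rocs(rocs: dict[str, classify.ROCResult], out: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for name, roc in rocs.items():
        ax.plot(roc.fpr_grid, roc.tpr_values, label=f"{name} (AUC {roc.auc:.3f})")
        ax.fill_between(roc.fpr_grid, roc.tpr_lower, roc.tpr_upper, alpha=0.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def _roc_summary(roc: classify.ROCResult) -> dict:
    return {
        "auc": roc.auc,
        "n_boot": roc.n_boot,
        "tpr_at_fpr_0.1": roc.tpr_at_fpr(0.1),
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path, plots: bool = True) -> dict:
    """Run every stage and write the report bundle to ``out_dir``.

    Emits correlation heatmaps, the ranked feature table, the cumulative
    separability curve, a 2-D PCA embedding, experiment 1 and 2 ROC
    curves, and a machine-readable ``results.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_names = ["simulate", "featmatrix", "split1", "eval1", "split2", "eval2"]
    seeds = dict(zip(stage_names, np.random.SeedSequence(config.seed).spawn(len(stage_names))))

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    case_table, control_table, data_prov = _load_tables(config)

    case_corr = stage("correlation", corrfeat.cohort_correlation, case_table)
    control_corr = stage("correlation", corrfeat.cohort_correlation, control_table)
    diff = corrfeat.correlation_difference(case_corr, control_corr, fisher_z=config.fisher_z)
    features = stage("features", corrfeat.select_top_features, diff, config.k_features,
                     case_table.atlas)

    fm = stage(
        "featmatrix",
        corrfeat.build_feature_matrix,
        case_table,
        control_table,
        features,
        config.n_subsets_per_cohort,
        config.g,
        _stage_seed(seeds["featmatrix"]),
    )

    curve = stage("hpd", hpdiv.hpd_feature_curve, fm)
    hpd_full = hpdiv.hp_divergence(
        fm.values[fm.label_array() == CASE], fm.values[fm.label_array() == CONTROL]
    )
    coords = classify.pca_embed(fm.values, dims=2)

    grid = np.asarray(config.penalty_grid, float) if config.penalty_grid else None

    # Experiment 1: overlapping subjects
    plan1 = stage(
        "split1",
        classify.split_experiment1,
        fm,
        config.n_train_rows,
        config.n_test_rows,
        _stage_seed(seeds["split1"]),
    )
    train1, test1 = fm.rows(plan1.train_rows), fm.rows(plan1.test_rows)
    model1 = stage(
        "fit1",
        classify.fit_sparse_linear,
        train1.values,
        train1.label_array(),
        grid,
        config.cv_folds,
        _stage_seed(seeds["eval1"]),
        config.loss,
    )
    roc1 = classify.roc_with_bootstrap(model1, test1, config.n_boot, _stage_seed(seeds["eval1"]))

    # Experiment 2: subject-disjoint
    train2, test2, plan2 = stage(
        "split2",
        classify.split_experiment2,
        case_table,
        control_table,
        features,
        config.n_train_case_subjects,
        config.n_train_control_subjects,
        config.n_train_rows,
        config.n_test_rows,
        config.g,
        _stage_seed(seeds["split2"]),
    )
    model2 = stage(
        "fit2",
        classify.fit_sparse_linear,
        train2.values,
        train2.label_array(),
        grid,
        config.cv_folds,
        _stage_seed(seeds["eval2"]),
        config.loss,
    )
    roc2 = classify.roc_with_bootstrap(model2, test2, config.n_boot, _stage_seed(seeds["eval2"]))

    results = {
        "config": asdict(config),
        "data": data_prov,
        "features": features.to_frame().to_dict(orient="records"),
        "separability_curve": {
            "feature_counts": curve.feature_counts.tolist(),
            "separability": curve.separability_values.tolist(),
        },
        "hpd_all_features": {
            "cross_edges": hpd_full.cross_edges,
            "divergence": hpd_full.divergence,
            "separability": hpd_full.separability,
        },
        "experiment1": {
            **_roc_summary(roc1),
            "penalty": model1.penalty,
            "n_active_features": model1.n_active_features,
            "n_train_rows": len(plan1.train_rows),
            "n_test_rows": len(plan1.test_rows),
        },
        "experiment2": {
            **_roc_summary(roc2),
            "penalty": model2.penalty,
            "n_active_features": model2.n_active_features,
            "n_train_rows": train2.n_rows,
            "n_test_rows": test2.n_rows,
            "n_train_subjects": len(plan2.train_subject_pool),
            "n_test_subjects": len(plan2.test_subject_pool),
        },
    }

    (out_dir / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    features.to_tsv(out_dir / "features.tsv")
    fm.to_csv(out_dir / "feature_matrix.csv", out_dir / "feature_matrix_provenance.json")
    np.savetxt(
        out_dir / "separability_curve.tsv",
        np.column_stack([curve.feature_counts, curve.separability_values]),
        delimiter="\t",
        header="n_features\tseparability",
        comments="",
    )
    if plots:
        _plot_correlations(
            case_corr.values, control_corr.values, diff, out_dir / "correlations.png"
        )
        _plot_curve(curve, out_dir / "separability_curve.png")
        _plot_embedding(coords, fm.labels, out_dir / "pca_embedding.png")
        _plot_rocs({"experiment 1": roc1, "experiment 2": roc2}, out_dir / "roc.png")
    logger.info("pipeline complete; results in %s", out_dir)
    return results
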