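"""Reporting: heatmaps, averaged ROC plots, and pipeline orchestration.

``run_pipeline`` executes one drug/ROI combination end to end — load (or
extract) the feature table, run the resampled selection, run the repeated
cross-validated evaluation — and writes every artifact plus a
machine-readable ``report.json``.  Two runs with the same config and seed
produce byte-identical metric files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .evaluation import HyperGrid, ValidationResult
from .features import ExtractionConfig, extract_all
from .model import DrugSignatureModel
from .preprocessing import correct_bias_field, match_histogram, resample_volume
from .selection import SelectionConfig

__all__ = [
    "RunConfig",
    "run_pipeline",
    "make_heatmap",
    "patient_clusters",
    "plot_mean_roc",
    "extract_cohort_table",
]

DISPLAY_Z_CLIP = 4.0  # display-only; analysis data are never clipped


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def _zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    sd = table.std(ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
    if keep.sum() == 0:
        raise ValueError("no feature with nonzero variance")
    t = table.loc[:, keep]
    return (t - t.mean()) / t.std(ddof=0)


def patient_clusters(table: pd.DataFrame, n_clusters: int = 2) -> np.ndarray:
    """Hierarchical patient clusters (average linkage, Euclidean) on
    z-scored features; the same ordering drives the heatmap rows."""
    z = _zscore_columns(table)
    return fcluster(linkage(z.to_numpy(), method="average"), n_clusters, "maxclust")


def make_heatmap(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    path: str | Path,
    drugs: tuple[str, ...] = ("statin", "omega3"),
) -> Path:
    """Clustered z-score heatmap with per-drug usage annotation bars."""
    import seaborn as sns

    z = _zscore_columns(table).clip(-DISPLAY_Z_CLIP, DISPLAY_Z_CLIP)
    coh = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    palette = {0: "#d9d9d9", 1: "#d7301f"}
    row_colors = pd.DataFrame(
        {d: coh.loc[z.index, d].map(palette) for d in drugs if d in coh.columns}
    )
    g = sns.clustermap(
        z,
        method="average",
        metric="euclidean",
        cmap="vlag",
        center=0,
        row_colors=row_colors if not row_colors.empty else None,
        xticklabels=False,
        yticklabels=False,
        figsize=(9, 7),
    )
    path = Path(path)
    g.savefig(path, dpi=120)
    plt.close(g.fig)
    return path


def plot_mean_roc(result: ValidationResult, path: str | Path) -> Path:
    """Averaged ROC curve with the chance diagonal and the mean AUC."""
    fpr, tpr = result.mean_roc()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, lw=2, label=f"mean AUC = {result.auc_mean:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# extraction over a phantom dataset
# ---------------------------------------------------------------------------

def extract_cohort_table(
    dataset_dir: str | Path,
    roi: str = "prostate",
    config: ExtractionConfig | None = None,
    bias_method: str = "smooth-divide",
    n_landmarks: int = 64,
    reference_id: str | None = None,
) -> pd.DataFrame:
    """Preprocess and extract features for every phantom in a dataset dir.

    Order of operations: bias correction, histogram matching against the
    reference patient (default: first patient id), resampling to the
    config spacing, extraction.
    """
    from .synthetic import read_phantom

    config = config or ExtractionConfig()
    dataset_dir = Path(dataset_dir)
    cohort = pd.read_csv(dataset_dir / "cohort.csv")
    ids = list(cohort["patient_id"])
    if reference_id is None:
        reference_id = ids[0]

    ref_vol, ref_g, ref_p = read_phantom(dataset_dir, reference_id)
    ref_mask = {"prostate": ref_g, "peripheral": ref_p}[roi]
    reference = correct_bias_field(ref_vol, bias_method, mask=ref_mask)

    rows = {}
    for pid in ids:
        vol, gland, peri = read_phantom(dataset_dir, pid)
        mask = {"prostate": gland, "peripheral": peri}[roi]
        vol = correct_bias_field(vol, bias_method, mask=mask)
        vol = match_histogram(vol, reference, n_landmarks)
        vol_r, mask_r = resample_volume(vol, mask, config.target_spacing)
        rows[pid] = extract_all(vol_r, mask_r, config)
    table = pd.DataFrame(rows).T
    table.index.name = "patient_id"
    return table


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One drug/ROI pipeline run."""

    dataset: Path
    drug: str
    roi: str = "prostate"
    out_dir: Path = Path("radsig-out")
    seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    grid: HyperGrid = field(default_factory=HyperGrid)
    eval_rounds: int = 500
    folds: int = 3
    search_budget: int | None = 16
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    bias_method: str = "smooth-divide"
    n_landmarks: int = 64
    reference_id: str | None = None


def run_pipeline(config: RunConfig) -> dict:
    """Execute extract/load -> select -> evaluate and write all artifacts."""
    dataset = Path(config.dataset)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        cohort = pd.read_csv(dataset / "cohort.csv")
        if config.drug not in cohort.columns:
            raise ValueError(
                f"drug column {config.drug!r} missing from cohort "
                f"(columns: {[c for c in cohort.columns if c != 'patient_id']})"
            )
        if (dataset / "features.csv").exists():
            table = pd.read_csv(dataset / "features.csv", index_col="patient_id")
        else:
            stage = "extract"
            table = extract_cohort_table(
                dataset,
                config.roi,
                config.extraction,
                bias_method=config.bias_method,
                n_landmarks=config.n_landmarks,
                reference_id=config.reference_id,
            )
            table.to_csv(out / "features.csv")

        stage = "select+evaluate"
        model = DrugSignatureModel.from_dataframe(
            table,
            cohort,
            config.drug,
            selection=config.selection,
            grid=config.grid,
            eval_rounds=config.eval_rounds,
            folds=config.folds,
            search_budget=config.search_budget,
        )
        res = model.fit(seed=config.seed)

        stage = "report"
        res.frequency_table().to_csv(out / "selection_frequencies.csv", index=False)
        (out / "ranked_features.txt").write_text("\n".join(res.signature) + "\n")
        res.validation.records.to_csv(out / "validation_metrics.csv", index=False)
        fpr, tpr = res.mean_roc()
        pd.DataFrame({"fpr": fpr, "mean_tpr": tpr}).to_csv(
            out / "mean_roc.csv", index=False
        )
        plot_mean_roc(res.validation, out / "mean_roc.png")
        try:
            make_heatmap(table, cohort, out / "heatmap.png", drugs=(config.drug,))
        except ValueError as err:
            warnings.warn(f"heatmap skipped: {err}")

        report = {
            "drug": config.drug,
            "roi": config.roi,
            "seed": config.seed,
            "selection_rounds": config.selection.rounds,
            "eval_rounds": config.eval_rounds,
            "folds": config.folds,
            "metrics": res.validation.summary_dict(),
            "signature": res.signature,
            "files": sorted(
                {p.name for p in out.iterdir() if p.is_file()} | {"report.json"}
            ),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return report
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err
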