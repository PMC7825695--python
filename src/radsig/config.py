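"""Flat YAML run configuration.

The config file is a flat mapping with dotted keys, e.g.::

    drug: statin
    roi: peripheral
    seed: 7
    preprocessing.bias_method: smooth-divide
    preprocessing.n_landmarks: 64
    extraction.bin_width: 25
    extraction.spacing_mm: [2, 2, 2]
    selection.rounds: 1000
    evaluation.rounds: 500

Unknown keys are errors (fail fast), so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .evaluation import HyperGrid
from .features import ExtractionConfig
from .selection import SelectionConfig

KNOWN_KEYS = {
    "drug",
    "roi",
    "seed",
    "preprocessing.bias_method",
    "preprocessing.n_landmarks",
    "preprocessing.reference_id",
    "extraction.bin_width",
    "extraction.spacing_mm",
    "extraction.log_sigma_mm",
    "extraction.wavelet_family",
    "extraction.glcm_distance",
    "selection.rounds",
    "selection.subsample_fraction",
    "selection.fdr_threshold",
    "selection.correlation_threshold",
    "selection.delta_auc",
    "selection.top_k",
    "evaluation.rounds",
    "evaluation.folds",
    "evaluation.search_budget",
}


def load_config(path: str | Path) -> dict:
    """Read and validate a flat config mapping; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    unknown = set(raw) - KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; known keys: "
            f"{sorted(KNOWN_KEYS)}"
        )
    return raw


def build_run_config(mapping: dict, dataset: Path, out_dir: Path):
    """Turn a validated flat mapping into a :class:`~radsig.report.RunConfig`."""
    from .report import RunConfig

    g = mapping.get
    seed = int(g("seed", 0))
    extraction = ExtractionConfig(
        bin_width=float(g("extraction.bin_width", 25.0)),
        target_spacing=tuple(g("extraction.spacing_mm", (2.0, 2.0, 2.0))),
        log_sigma_mm=float(g("extraction.log_sigma_mm", 5.0)),
        wavelet_family=str(g("extraction.wavelet_family", "coif1")),
        glcm_distance=int(g("extraction.glcm_distance", 1)),
    )
    selection = SelectionConfig(
        rounds=int(g("selection.rounds", 1000)),
        subsample_fraction=float(g("selection.subsample_fraction", 2.0 / 3.0)),
        fdr_threshold=float(g("selection.fdr_threshold", 0.5)),
        correlation_threshold=float(g("selection.correlation_threshold", 0.8)),
        delta_auc=float(g("selection.delta_auc", 0.01)),
        top_k=int(g("selection.top_k", 10)),
        seed=seed,
    )
    budget = g("evaluation.search_budget", 16)
    return RunConfig(
        dataset=Path(dataset),
        drug=str(g("drug", "statin")),
        roi=str(g("roi", "prostate")),
        out_dir=Path(out_dir),
        seed=seed,
        selection=selection,
        grid=HyperGrid(),
        eval_rounds=int(g("evaluation.rounds", 500)),
        folds=int(g("evaluation.folds", 3)),
        search_budget=None if budget in (None, "none") else int(budget),
        extraction=extraction,
        bias_method=str(g("preprocessing.bias_method", "smooth-divide")),
        n_landmarks=int(g("preprocessing.n_landmarks", 64)),
        reference_id=g("preprocessing.reference_id", None),
    )
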