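"""Model-style front end to the selection + evaluation pipeline.

:class:`DrugSignatureModel` binds a patient-by-feature table to a binary
medication label; :meth:`~DrugSignatureModel.fit` runs the resampled
feature-selection protocol followed by the repeated cross-validated
gradient-boosting evaluation and returns a
:class:`DrugSignatureResults` carrying the selection frequencies, the
ranked signature, the per-test AUC/PRAUC records, and a text
``summary()``.

    >>> model = DrugSignatureModel.from_dataframe(table, cohort, drug="statin")
    >>> res = model.fit(seed=7)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import HyperGrid, ValidationResult, cross_validate
from .selection import SelectionConfig, SelectionResult, run_selection, top_features

__all__ = ["DrugSignatureModel", "DrugSignatureResults"]


class DrugSignatureModel:
    """Radiomics signature model for one drug/ROI combination.

    Parameters
    ----------
    features : DataFrame
        Patients x features; the index identifies patients.
    labels : Series or array of {0, 1}
        Binary usage flag per patient, aligned with ``features``.
    selection : SelectionConfig, optional
        Parameters of the resampled feature selection (1000 rounds by
        default; lower for quick runs).
    grid : HyperGrid, optional
        Hyperparameter search space for evaluation.
    eval_rounds, folds : int
        Repeated-CV protocol size; the reference protocol is 500 rounds x
        3 folds = 1500 validation tests.
    search_budget : int or None
        Number of grid settings examined per training fold (None = all).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels,
        drug: str = "drug",
        selection: SelectionConfig | None = None,
        grid: HyperGrid | None = None,
        eval_rounds: int = 500,
        folds: int = 3,
        search_budget: int | None = 16,
    ) -> None:
        y = np.asarray(labels).astype(int)
        if len(y) != len(features):
            raise ValueError("labels and features disagree on patient count")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(f"label {drug!r} has a single class")
        self.features = features
        self.labels = y
        self.drug = drug
        self.selection_config = selection or SelectionConfig()
        self.grid = grid or HyperGrid()
        self.eval_rounds = int(eval_rounds)
        self.folds = int(folds)
        self.search_budget = search_budget

    @classmethod
    def from_dataframe(
        cls,
        features: pd.DataFrame,
        cohort: pd.DataFrame,
        drug: str,
        **kwargs,
    ) -> "DrugSignatureModel":
        """Build from a feature table and a cohort table sharing patient ids."""
        if drug not in cohort.columns:
            raise ValueError(
                f"drug column {drug!r} not in cohort columns {list(cohort.columns)}"
            )
        cohort = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
        labels = cohort.loc[features.index, drug]
        return cls(features, labels, drug=drug, **kwargs)

    def fit(self, seed: int = 0) -> "DrugSignatureResults":
        """Run selection then evaluation; everything derives from ``seed``."""
        sel_cfg = self.selection_config
        if sel_cfg.seed != seed:
            sel_cfg = SelectionConfig(**{**sel_cfg.__dict__, "seed": seed})
        sel = run_selection(self.features, self.labels, sel_cfg)
        max_k = max(self.grid.n_top_features)
        ranked = sel.ranking()[:max_k]
        val = cross_validate(
            self.features,
            self.labels,
            ranked,
            grid=self.grid,
            rounds=self.eval_rounds,
            folds=self.folds,
            seed=seed + 1,
            search_budget=self.search_budget,
        )
        return DrugSignatureResults(self, sel, val, seed)


@dataclass
class DrugSignatureResults:
    """Fitted signature: selection frequencies plus validation metrics."""

    model: DrugSignatureModel = field(repr=False)
    selection: SelectionResult = field(repr=False)
    validation: ValidationResult = field(repr=False)
    seed: int = 0

    @property
    def signature(self) -> list[str]:
        """Top-k features by selection frequency."""
        return top_features(self.selection, self.model.selection_config.top_k)

    @property
    def auc_mean(self) -> float:
        return self.validation.auc_mean

    @property
    def auc_sd(self) -> float:
        return self.validation.auc_sd

    @property
    def prauc_mean(self) -> float:
        return self.validation.prauc_mean

    def mean_roc(self, n_grid: int = 101):
        return self.validation.mean_roc(n_grid)

    def frequency_table(self) -> pd.DataFrame:
        """Selection frequencies (count and fraction of rounds), ranked."""
        freq = self.selection.frequencies
        ranked = self.selection.ranking()
        return pd.DataFrame(
            {
                "feature": ranked,
                "count": [int(freq[f]) for f in ranked],
                "fraction": [freq[f] / self.selection.rounds for f in ranked],
            }
        )

    def summary(self) -> str:
        m = self.model
        v = self.validation
        lines = [
            "Radiomics drug-usage signature",
            "=" * 62,
            f"drug / label:        {m.drug}",
            f"patients:            {len(m.labels)}  "
            f"({int(m.labels.sum())} users, {int((1 - m.labels).sum())} non-users)",
            f"features screened:   {m.features.shape[1]}",
            f"selection rounds:    {self.selection.rounds}",
            f"validation tests:    {len(v.records)} "
            f"({m.eval_rounds} rounds x {m.folds} folds)",
            f"master seed:         {self.seed}",
            "-" * 62,
            f"AUC   mean (sd):     {v.auc_mean:.3f} ({v.auc_sd:.3f})",
            f"PRAUC mean (sd):     {v.prauc_mean:.3f} ({v.prauc_sd:.3f})",
            "-" * 62,
            "signature (selection count / rounds):",
        ]
        freq = self.selection.frequencies
        for f in self.signature:
            lines.append(f"  {f:<48s} {int(freq[f]):>4d} / {self.selection.rounds}")
        lines.append("=" * 62)
        return "\n".join(lines)
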