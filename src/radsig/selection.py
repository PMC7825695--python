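"""Resampling-based feature selection.

The selection protocol draws two-thirds of the patients (stratified,
without replacement) for a configurable number of rounds — 1000 by
default.  Within each round:

1. a univariate one-way ANOVA (two groups, so equivalent to a pooled
   two-sample t-test) screens every feature;
2. features with a Benjamini-Hochberg FDR-adjusted p below a deliberately
   lenient threshold (default 0.5) survive;
3. survivors with |Pearson r| above 0.8 are grouped into connected
   components and only the lowest-p member of each cluster is kept;
4. sequential floating forward selection (SFFS) with a gradient-boosting
   learner adds features while each addition improves the internally
   cross-validated AUC by more than 0.01, with conditional backward
   removal.

Features are then ranked by how often they were selected across rounds;
the top 10 form the signature passed to evaluation.  All tie-breaks are
lexicographic on the feature name so results are platform-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import f as f_dist

from .evaluation import GBMClassifier, compute_auc

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "anova_screen",
    "fdr_adjust",
    "cluster_correlated",
    "sffs_select",
    "run_selection",
    "top_features",
]


DEFAULT_SFFS_LEARNER = {
    "n_trees": 20,
    "shrinkage": 0.2,
    "interaction_depth": 2,
    "min_node_size": 5,
    "bag_fraction": 1.0,
}


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the resampled selection protocol."""

    rounds: int = 1000
    subsample_fraction: float = 2.0 / 3.0
    fdr_threshold: float = 0.5
    correlation_threshold: float = 0.8
    delta_auc: float = 0.01
    top_k: int = 10
    max_subset_size: int = 10
    sffs_folds: int = 3
    learner_settings: dict = field(default_factory=lambda: dict(DEFAULT_SFFS_LEARNER))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        for name in ("fdr_threshold", "correlation_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------

def anova_screen(table: pd.DataFrame, labels: np.ndarray | pd.Series) -> pd.Series:
    """One-way two-group ANOVA F-test p-value per feature (vectorized).

    Zero-variance features get p = 1 by convention.  Raises when only one
    class is present or fewer than 3 samples are available.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < 3:
        raise ValueError("ANOVA screen needs n >= 3")
    n1 = int((y == 1).sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both label classes must be present")
    X = table.to_numpy(dtype=np.float64)
    mean1 = X[y == 1].mean(axis=0)
    mean0 = X[y == 0].mean(axis=0)
    grand = X.mean(axis=0)
    ssb = n1 * (mean1 - grand) ** 2 + n0 * (mean0 - grand) ** 2
    sst = ((X - grand) ** 2).sum(axis=0)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ssb / (ssw / (n - 2))
        p = f_dist.sf(F, 1, n - 2)
    p = np.where(sst <= 1e-300, 1.0, p)  # constant feature: no evidence
    p = np.where(np.isnan(p), 1.0, p)
    return pd.Series(p, index=table.columns, name="p_value")


def fdr_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p_values
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index, name="p_adjusted")
    return out


# ---------------------------------------------------------------------------
# correlation clustering
# ---------------------------------------------------------------------------

def cluster_correlated(
    table: pd.DataFrame,
    surviving: list[str],
    p_values: pd.Series,
    threshold: float = 0.8,
) -> list[str]:
    """Keep one representative (lowest p, ties lexicographic) per connected
    component of the |Pearson r| > threshold graph."""
    if not surviving:
        raise ValueError("no surviving features to cluster")
    if len(surviving) == 1:
        return list(surviving)
    X = table[surviving].to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance column: treated as r=0
    adj = np.abs(corr) > threshold
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    reps = []
    names = np.array(surviving)
    for c in range(n_comp):
        members = names[comp == c]
        best = min(members, key=lambda f: (p_values[f], f))
        reps.append(best)
    return sorted(reps)


# ---------------------------------------------------------------------------
# SFFS
# ---------------------------------------------------------------------------

def sffs_select(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    candidates: list[str],
    delta_auc: float = 0.01,
    learner_settings: dict | None = None,
    seed: int = 0,
    max_subset_size: int = 10,
    n_folds: int = 3,
) -> list[str]:
    """Sequential floating forward selection scored by cross-validated AUC.

    Forward steps add the candidate whose inclusion maximizes the
    ``n_folds``-fold CV AUC of the gradient-boosting learner and must
    improve it by more than ``delta_auc``; after each addition, backward
    steps remove members (never the one just added) while removal beats
    the best AUC previously seen at the smaller size.  Candidate order and
    all tie-breaks are lexicographic; a learner failure scores 0.5.
    """
    from sklearn.model_selection import StratifiedKFold

    if not candidates:
        raise ValueError("candidate set is empty")
    candidates = sorted(candidates)
    y = np.asarray(labels).astype(int)
    settings = dict(DEFAULT_SFFS_LEARNER, **(learner_settings or {}))
    X_all = table[candidates].to_numpy(dtype=np.float64)
    col = {f: i for i, f in enumerate(candidates)}

    n_folds = min(n_folds, int((y == 1).sum()), int((y == 0).sum()))
    if n_folds < 2:
        raise ValueError("need at least 2 samples per class for internal CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    folds = list(skf.split(X_all, y))

    cache: dict[frozenset, float] = {}

    def score(subset: tuple[str, ...]) -> float:
        key = frozenset(subset)
        if key in cache:
            return cache[key]
        idx = [col[f] for f in subset]
        aucs = []
        for tr, te in folds:
            try:
                model = GBMClassifier(**settings, seed=seed).fit(X_all[tr][:, idx], y[tr])
                aucs.append(compute_auc(model.predict_proba(X_all[te][:, idx]), y[te]))
            except ValueError:
                aucs.append(0.5)
        val = float(np.mean(aucs))
        cache[key] = val
        return val

    selected: list[str] = []
    current = 0.5  # chance level: an empty model has no discrimination
    best_at_size: dict[int, float] = {0: current}

    while len(selected) < max_subset_size:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        scores = [score(tuple(selected + [c])) for c in remaining]
        best_i = int(np.argmax(scores))
        if scores[best_i] - current <= delta_auc:
            break
        just_added = remaining[best_i]
        selected.append(just_added)
        current = scores[best_i]
        best_at_size[len(selected)] = max(
            best_at_size.get(len(selected), -np.inf), current
        )
        # conditional backward (floating) phase
        while len(selected) > 2:
            removable = [f for f in selected if f != just_added]
            back = [score(tuple(f2 for f2 in selected if f2 != f)) for f in removable]
            bi = int(np.argmax(back))
            if back[bi] > best_at_size.get(len(selected) - 1, -np.inf):
                selected.remove(removable[bi])
                current = back[bi]
                best_at_size[len(selected)] = current
            else:
                break
    return selected


# ---------------------------------------------------------------------------
# the resampling loop
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Selection frequencies over all rounds plus the per-round log."""

    frequencies: pd.Series  # index = all table columns; counts over rounds
    rounds: int
    per_round: list[dict] = field(repr=False)
    config: SelectionConfig | None = field(default=None, repr=False)

    def ranking(self) -> list[str]:
        """All features ordered by frequency (desc), ties lexicographic."""
        order = sorted(
            self.frequencies.index, key=lambda f: (-self.frequencies[f], f)
        )
        return list(order)


def top_features(result: SelectionResult, k: int = 10) -> list[str]:
    """The k highest-frequency features (nonzero frequency only).

    Warns when ties straddle the k-boundary or when fewer than k features
    were ever selected (all of them are then returned).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = [f for f in result.ranking() if result.frequencies[f] > 0]
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} features have nonzero selection frequency; "
            f"returning all of them (requested {k})"
        )
        return ranked
    freqs = result.frequencies
    if len(ranked) > k and freqs[ranked[k - 1]] == freqs[ranked[k]]:
        warnings.warn(
            f"tie at the top-{k} boundary (frequency {freqs[ranked[k]]}); "
            "broken lexicographically"
        )
    return ranked[:k]


def _stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a label-stratified subsample of ceil(fraction * n)."""
    n = len(y)
    k = int(np.ceil(fraction * n))
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    k1 = min(len(pos), max(1, int(round(k * len(pos) / n))))
    k0 = min(len(neg), max(1, k - k1))
    take = np.concatenate(
        [
            rng.choice(pos, size=k1, replace=False),
            rng.choice(neg, size=k0, replace=False),
        ]
    )
    return np.sort(take)


def run_selection(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Run the full resampled selection protocol.

    Per round: stratified two-thirds subsample, ANOVA screen, FDR filter,
    correlation clustering, SFFS; the selected sets are accumulated into
    per-feature frequencies.  Fully reproducible from ``config.seed``.
    """
    config = config or SelectionConfig()
    y = np.asarray(labels).astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 patients per class")

    freq = pd.Series(0, index=table.columns, dtype=np.int64)
    log: list[dict] = []
    children = np.random.SeedSequence(config.seed).spawn(config.rounds)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            idx = _stratified_subsample(y, config.subsample_fraction, rng)
            sub_X = table.iloc[idx]
            sub_y = y[idx]
            p = anova_screen(sub_X, sub_y)
            p_adj = fdr_adjust(p)
            surviving = sorted(p.index[np.asarray(p_adj) < config.fdr_threshold])
            if surviving:
                reps = cluster_correlated(
                    sub_X, surviving, p, config.correlation_threshold
                )
                chosen = sffs_select(
                    sub_X,
                    sub_y,
                    reps,
                    delta_auc=config.delta_auc,
                    learner_settings=config.learner_settings,
                    seed=int(rng.integers(2**31)),
                    max_subset_size=config.max_subset_size,
                    n_folds=config.sffs_folds,
                )
            else:
                reps, chosen = [], []
        except Exception as err:
            raise RuntimeError(f"selection failed in round {r}: {err}") from err
        for f in chosen:
            freq[f] += 1
        log.append(
            {
                "round": r,
                "n_subsample": int(len(idx)),
                "n_after_fdr": len(surviving),
                "n_after_cluster": len(reps),
                "selected": list(chosen),
            }
        )
    return SelectionResult(freq, config.rounds, log, config)
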