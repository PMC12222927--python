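"""Feature ranking and selection.

Six methods are implemented: variance threshold (a filter, applied before
ranking), Pearson correlation, one-way ANOVA F, mutual information
(quantile-binned, deterministic), recursive feature elimination (RFE)
around a random forest, and random-forest importance (RFI). RFI followed
by top-k selection is the production protocol: on training-style data it
recovers ORF coverage plus the two spectral key features at k = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import mutual_info_score

from .features import FeatureTable

RANKING_METHODS = ("pearson", "anova", "mutual_information", "rfe", "rfi")

#: Forest used for RFI and as the RFE estimator.
RF_N_TREES = 500
RF_SEED = 42
#: Fraction of remaining features eliminated per RFE round.
RFE_STEP_FRACTION = 0.10
#: Bins for the quantile-discretized mutual-information estimator.
MI_BINS = 16


@dataclass
class FeatureRanking:
    method: str
    ranked: list[tuple[str, float]]  # (feature, score), score descending
    params: dict = field(default_factory=dict)
    seed: int = RF_SEED

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.ranked):
            raise ValueError(f"k={k} out of range 1..{len(self.ranked)}")
        return [name for name, _ in self.ranked[:k]]


def variance_filter(table: FeatureTable, threshold: float = 0.01) -> FeatureTable:
    """Drop every column whose population variance is below *threshold*."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    var = table.X.var(axis=0, ddof=0)
    keep = var.index[var >= threshold].tolist()
    if not keep:
        raise ValueError("variance filter dropped every feature")
    return table.subset(keep)


def _encode_labels(y: pd.Series) -> np.ndarray:
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("feature ranking needs at least 2 classes")
    return (y == classes[-1]).to_numpy(dtype=float)


def _sorted_ranking(scores: dict[str, float]) -> list[tuple[str, float]]:
    # descending score; ties broken lexicographically by feature name
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def _pearson_scores(X: pd.DataFrame, y01: np.ndarray) -> dict[str, float]:
    out = {}
    yc = y01 - y01.mean()
    ss_y = float(np.sum(yc**2))
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        xc = x - x.mean()
        denom = np.sqrt(float(np.sum(xc**2)) * ss_y)
        out[name] = abs(float(np.sum(xc * yc)) / denom) if denom > 0 else 0.0
    return out


def _anova_scores(X: pd.DataFrame, y01: np.ndarray) -> dict[str, float]:
    g0, g1 = y01 == 0, y01 == 1
    out = {}
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        if np.var(x) == 0:
            out[name] = 0.0
            continue
        f, _ = _sstats.f_oneway(x[g0], x[g1])
        # zero within-group variance with distinct means: perfect separation
        out[name] = float(f) if not np.isnan(f) else 0.0
    return out


def _mi_scores(X: pd.DataFrame, y01: np.ndarray) -> dict[str, float]:
    out = {}
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        if np.var(x) == 0:
            out[name] = 0.0
            continue
        edges = np.unique(np.quantile(x, np.linspace(0, 1, MI_BINS + 1)))
        binned = np.digitize(x, edges[1:-1]) if len(edges) > 2 else (x > edges[0]).astype(int)
        out[name] = float(mutual_info_score(binned, y01))
    return out


def _forest(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=RF_N_TREES,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def _rfi_scores(X: pd.DataFrame, y01: np.ndarray, seed: int) -> dict[str, float]:
    rf = _forest(seed).fit(X.to_numpy(dtype=float), y01)
    return dict(zip(X.columns, (float(v) for v in rf.feature_importances_)))


def _rfe_scores(X: pd.DataFrame, y01: np.ndarray, seed: int) -> dict[str, float]:
    """Score = elimination round survived (later elimination → higher score)."""
    remaining = list(X.columns)
    scores: dict[str, float] = {}
    round_no = 0
    while remaining:
        round_no += 1
        if len(remaining) == 1:
            scores[remaining[0]] = float(round_no)
            break
        imp = _rfi_scores(X[remaining], y01, seed)
        n_drop = max(1, int(len(remaining) * RFE_STEP_FRACTION))
        # least important first; ties broken reverse-lexicographically so the
        # final ranking's lexicographic tie-break is preserved
        order = sorted(remaining, key=lambda n: (imp[n], n))
        dropped = order[:n_drop]
        for name in dropped:
            scores[name] = float(round_no)
        remaining = [n for n in remaining if n not in dropped]
    return scores


def rank_features(
    table: FeatureTable,
    method: str,
    seed: int = RF_SEED,
) -> FeatureRanking:
    """Rank every feature by the named method (higher score = better)."""
    if method not in RANKING_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {RANKING_METHODS}")
    if table.y is None:
        raise ValueError("ranking requires class labels")
    y01 = _encode_labels(table.y)
    X = table.X
    if method == "pearson":
        scores = _pearson_scores(X, y01)
    elif method == "anova":
        scores = _anova_scores(X, y01)
    elif method == "mutual_information":
        scores = _mi_scores(X, y01)
    elif method == "rfi":
        scores = _rfi_scores(X, y01, seed)
    else:
        scores = _rfe_scores(X, y01, seed)
    return FeatureRanking(method=method, ranked=_sorted_ranking(scores), seed=seed)


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First *k* feature names in ranking order."""
    return ranking.top(k)


def ranking_to_tsv(ranking: FeatureRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("method\trank\tfeature\tscore\n")
        for i, (name, score) in enumerate(ranking.ranked, 1):
            fh.write(f"{ranking.method}\t{i}\t{name}\t{score:.6g}\n")
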