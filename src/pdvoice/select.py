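"""Feature selection: four rankers, perturbation voting, one-SE subset size.

Four standard selectors rank the 132 dysphonia measures by their ability
to predict the (discretized) UPDRS response: LASSO (order of entry along
the L1 regularization path), minimum-redundancy-maximum-relevance (mutual
information with a greedy relevance-minus-redundancy criterion), ReliefF
(margin-based nearest-neighbour weights), and out-of-bag permutation
importance in a random forest.  Because single-shot rankings are
unstable, each selector is run on several perturbed (subsampled) versions
of the dataset and every run votes for its top-m features; features are
then ordered by votes (ties broken by mean rank, then name).  The final
subset size K is chosen by the one-standard-error rule on a
cross-validated error curve: the smallest K whose mean error is within
one standard deviation of the global minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.metrics import mutual_info_score
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

ALGORITHMS = ("lasso", "mrmr", "relief", "rf_importance")

__all__ = ["FSResult", "rank_features", "vote_select", "choose_k_one_se", "ALGORITHMS"]


@dataclass
class FSResult:
    """Outcome of perturbation-voting feature selection."""

    algorithm: str
    rankings: list[list[str]]            # one full ranking per perturbation
    vote_counts: dict[str, int]
    aggregated_ranking: list[str]
    k: int
    top_m: int

    def __post_init__(self) -> None:
        if self.k > len(self.aggregated_ranking):
            raise ValueError("K exceeds the number of ranked features")

    @property
    def selected_subset(self) -> list[str]:
        return self.aggregated_ranking[: self.k]

    def subset(self, k: int) -> list[str]:
        return self.aggregated_ranking[:k]

    def report(self) -> str:
        lines = [
            f"feature selection: {self.algorithm}",
            f"perturbations: {len(self.rankings)}; votes per run: {self.top_m}; K = {self.k}",
            "rank  votes  feature",
        ]
        for i, name in enumerate(self.aggregated_ranking[: max(self.k, self.top_m)], 1):
            lines.append(f"{i:4d}  {self.vote_counts.get(name, 0):5d}  {name}")
        return "\n".join(lines)


def _as_frame(X, feature_names: Optional[Sequence[str]]) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(np.asarray(X).shape[1])]
    return pd.DataFrame(np.asarray(X, dtype=float), columns=list(feature_names))


def _validate(X: pd.DataFrame, y: np.ndarray) -> tuple[np.ndarray, list[str]]:
    values = X.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("rank_features requires imputed (complete) features")
    if np.unique(y).size < 2:
        raise ValueError("response is constant; ranking undefined")
    constant = [c for c, s in zip(X.columns, values.std(axis=0)) if s == 0]
    if constant:
        logger.info("constant feature columns ranked last: %s", constant)
    return values, constant


def _order(scores: dict[str, float], constant: list[str]) -> list[str]:
    """Descending by score, ties by name; constant columns last."""
    informative = [n for n in scores if n not in constant]
    ranked = sorted(informative, key=lambda n: (-scores[n], n))
    return ranked + sorted(constant)


# ------------------------------------------------------------------ rankers
def _rank_lasso(values: np.ndarray, y: np.ndarray, names: list[str]) -> dict[str, float]:
    std = values.std(axis=0)
    std[std == 0] = 1.0
    Xs = (values - values.mean(axis=0)) / std
    yc = y - y.mean()
    _, coefs, _ = lasso_path(Xs, yc, alphas=100, eps=1e-3)
    entry = np.full(len(names), np.inf)
    nz = np.abs(coefs) > 1e-12
    for j in range(len(names)):
        hits = np.nonzero(nz[j])[0]
        if hits.size:
            entry[j] = hits[0]
    # earlier entry on the path = more relevant; final |coef| breaks ties
    final = np.abs(coefs[:, -1])
    return {n: -float(entry[j]) + 1e-9 * float(final[j]) for j, n in enumerate(names)}


def _discretize_bins(col: np.ndarray, bins: int = 10) -> np.ndarray:
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), col)


def _rank_mrmr(values: np.ndarray, y: np.ndarray, names: list[str]) -> dict[str, float]:
    n_feat = values.shape[1]
    disc = np.column_stack([_discretize_bins(values[:, j]) for j in range(n_feat)])
    rel = np.array([mutual_info_score(disc[:, j], y) for j in range(n_feat)])
    selected: list[int] = []
    remaining = list(range(n_feat))
    red_sum = np.zeros(n_feat)
    scores: dict[str, float] = {}
    for step in range(n_feat):
        if selected:
            last = selected[-1]
            for j in remaining:
                red_sum[j] += mutual_info_score(disc[:, j], disc[:, last])
            crit = [rel[j] - red_sum[j] / len(selected) for j in remaining]
        else:
            crit = [rel[j] for j in remaining]
        pick_pos = int(np.argmax(crit))
        j = remaining.pop(pick_pos)
        selected.append(j)
        scores[names[j]] = float(n_feat - step)   # rank position as score
    return scores


def _rank_relief(values: np.ndarray, y: np.ndarray, names: list[str],
                 k_neighbors: int = 10) -> dict[str, float]:
    span = values.max(axis=0) - values.min(axis=0)
    span[span == 0] = 1.0
    Xn = (values - values.min(axis=0)) / span
    n = Xn.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    priors = counts / n
    by_class = {c: np.nonzero(y == c)[0] for c in classes}
    nn = {c: NearestNeighbors(n_neighbors=min(k_neighbors + 1, idx.size)).fit(Xn[idx])
          for c, idx in by_class.items()}
    W = np.zeros(Xn.shape[1])
    for i in range(n):
        ci = y[i]
        for c, idx in by_class.items():
            k_eff = min(k_neighbors, idx.size - (1 if c == ci else 0))
            if k_eff < 1:
                continue
            _, neigh = nn[c].kneighbors(Xn[i][None, :], n_neighbors=min(k_neighbors + 1, idx.size))
            cand = idx[neigh[0]]
            cand = cand[cand != i][:k_eff]
            if cand.size == 0:
                continue
            diff = np.abs(Xn[cand] - Xn[i]).mean(axis=0)
            if c == ci:
                W -= diff / n
            else:
                pc = priors[np.nonzero(classes == c)[0][0]]
                pi = priors[np.nonzero(classes == ci)[0][0]]
                W += (pc / (1.0 - pi)) * diff / n
    return {n_: float(w) for n_, w in zip(names, W)}


def _rank_rf_importance(values: np.ndarray, y: np.ndarray, names: list[str],
                        n_trees: int = 500, seed: int = 0) -> dict[str, float]:
    """Out-of-bag permutation importance with an explicit bagging loop."""
    rng = np.random.default_rng(seed)
    n, m = values.shape
    importances = np.zeros(m)
    counts = np.zeros(m)
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size < 2:
            continue
        tree = DecisionTreeClassifier(max_features="sqrt",
                                      random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(values[boot], y[boot])
        base = float(np.mean(tree.predict(values[oob]) == y[oob]))
        X_oob = values[oob]
        order = rng.permutation(oob.size)
        # one predict call for all m permuted copies: block j is X_oob
        # with column j permuted
        stacked = np.tile(X_oob, (m, 1))
        rows = np.arange(oob.size)
        for j in range(m):
            stacked[j * oob.size + rows, j] = X_oob[order, j]
        pred = tree.predict(stacked).reshape(m, oob.size)
        acc = (pred == y[oob][None, :]).mean(axis=1)
        importances += base - acc
        counts += 1
    counts[counts == 0] = 1
    return {n_: float(v / c) for n_, v, c in zip(names, importances, counts)}


def rank_features(
    X,
    y,
    algorithm: str,
    params: Optional[dict] = None,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> list[str]:
    """Total order over features, most relevant first.

    ``y`` must be the discretized (integer-class) response for the
    classifier-based rankers.  Deterministic given the seed; invariant to
    the order of the feature columns (ties break by feature name).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    frame = _as_frame(X, feature_names)
    # canonical column order so rankings do not depend on input layout
    frame = frame[sorted(frame.columns)]
    y = np.asarray(y)
    values, constant = _validate(frame, y)
    names = list(frame.columns)
    params = params or {}
    if algorithm == "lasso":
        scores = _rank_lasso(values, y, names)
    elif algorithm == "mrmr":
        scores = _rank_mrmr(values, y, names)
    elif algorithm == "relief":
        scores = _rank_relief(values, y, names, k_neighbors=params.get("k_neighbors", 10))
    else:
        scores = _rank_rf_importance(values, y, names,
                                     n_trees=params.get("n_trees", 500), seed=seed)
    return _order(scores, constant)


def vote_select(
    X,
    y,
    algorithm: str,
    n_perturbations: int = 10,
    subsample_frac: float = 0.9,
    top_m: int = 30,
    seed: int = 0,
    params: Optional[dict] = None,
    k: Optional[int] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> FSResult:
    """Perturbation-voting feature selection.

    Runs ``rank_features`` on ``n_perturbations`` subsampled datasets;
    each run votes for its ``top_m`` features.  The aggregated ranking
    sorts by votes, breaking ties by mean rank across runs and then by
    name; the provisional subset is its first ``k`` (default ``top_m``)
    entries until an error curve fixes K via the one-SE rule.
    """
    if n_perturbations < 2:
        raise ValueError("voting requires at least 2 perturbations")
    frame = _as_frame(X, feature_names)
    y = np.asarray(y)
    n = len(frame)
    n_sub = int(round(subsample_frac * n))
    if n_sub < 10:
        raise ValueError("subsample too small for ranking")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x51]))
    names = sorted(frame.columns)
    votes = {name: 0 for name in names}
    rank_sums = {name: 0.0 for name in names}
    rankings: list[list[str]] = []
    for p in range(n_perturbations):
        idx = rng.choice(n, size=n_sub, replace=False)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ranking = rank_features(frame.iloc[idx], y[idx], algorithm,
                                params=params, seed=sub_seed)
        rankings.append(ranking)
        for pos, name in enumerate(ranking):
            rank_sums[name] += pos
            if pos < top_m:
                votes[name] += 1
    mean_rank = {name: rank_sums[name] / n_perturbations for name in names}
    aggregated = sorted(names, key=lambda nm: (-votes[nm], mean_rank[nm], nm))
    k_final = int(k) if k is not None else int(top_m)
    return FSResult(
        algorithm=algorithm,
        rankings=rankings,
        vote_counts=votes,
        aggregated_ranking=aggregated,
        k=min(k_final, len(aggregated)),
        top_m=top_m,
    )


def choose_k_one_se(mae_by_k: Sequence[tuple[int, float, float]]) -> int:
    """One-standard-error rule on an error curve of (K, mean MAE, sd MAE).

    Returns the smallest K whose mean MAE is at most the global minimum
    mean MAE plus the sd at the argmin.  Never exceeds the argmin K.
    """
    curve = list(mae_by_k)
    if not curve:
        raise ValueError("empty MAE curve")
    ks = [c[0] for c in curve]
    means = [c[1] for c in curve]
    sds = [c[2] for c in curve]
    i_min = int(np.argmin(means))
    threshold = means[i_min] + sds[i_min]
    eligible = [k for k, m in zip(ks, means) if m <= threshold]
    return int(min(eligible))
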