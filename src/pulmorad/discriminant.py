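"""Exhaustive low-dimensional linear-classifier search with AUROC ranking.

The classifier is a shrinkage-regularized linear discriminant: weights
``w = (S_pooled + lambda I)^-1 (mu_1 - mu_0)`` with
``lambda = 1e-3 tr(S)/k``, scored by the Mann-Whitney AUROC and Youden's
J-index at the optimal training cutoff.  Candidate feature subsets of size
1..4 are enumerated exhaustively; subsets are ranked by descending J, then
mean AUROC, then parsimony, then feature names.  Generalization is
estimated by stratified repeated hold-out (default 80/20 x 200) and by a
frozen-model evaluation on an independent test table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: warn when the subset count at max_dim exceeds this (desk-scale guard)
SEARCH_SPACE_WARN = 2 * 10**7


class SingleClassError(ValueError):
    pass


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
        raise SingleClassError("labels must contain both classes (0 and 1)")
    return y


def auroc(scores, y) -> float:
    """Mann-Whitney AUROC: P(case score > control score), ties count 1/2."""
    y = _check_binary(np.asarray(y))
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def youden(scores, y) -> tuple[float, float, float, float]:
    """Maximize sens + spec - 1 over score cutoffs (rule: positive if
    score >= cutoff).

    Candidate cutoffs are the midpoints between adjacent distinct scores
    plus the two open ends, so J >= 0 always; ties resolve to the lowest
    cutoff.  Returns ``(j, cutoff, sens, spec)``.
    """
    y = _check_binary(np.asarray(y))
    s = np.asarray(scores, dtype=float)
    order = np.argsort(s, kind="mergesort")
    ss, yy = s[order], y[order]
    n1 = int(yy.sum())
    n0 = yy.size - n1
    # cutoff below min: everyone positive
    cuts = [ss[0] - 1.0]
    distinct = np.nonzero(np.diff(ss) > 0)[0]
    cuts.extend((ss[i] + ss[i + 1]) / 2.0 for i in distinct)
    cuts.append(ss[-1] + 1.0)
    cum1 = np.concatenate([[0], np.cumsum(yy == 1)])
    cum0 = np.concatenate([[0], np.cumsum(yy == 0)])
    # position after the last score below each cutoff
    pos = [0] + [i + 1 for i in distinct] + [len(ss)]
    best = (-np.inf, np.inf, 0.0, 0.0)
    for cut, p in zip(cuts, pos):
        sens = (n1 - cum1[p]) / n1
        spec = cum0[p] / n0
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, cut, sens, spec)
    return tuple(float(v) for v in best)


@dataclass
class LinearModel:
    """A fitted linear discriminant on a named feature subset."""

    features: tuple[str, ...]
    weights: np.ndarray
    cutoff: float
    train_auc: float
    j_index: float
    sens: float = 0.0
    spec: float = 0.0

    def score(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise KeyError(f"test table lacks features: {missing}")
        return table[list(self.features)].to_numpy(float) @ self.weights


@dataclass
class CVEstimate:
    """Repeated-hold-out (or bootstrap) AUROC distribution summary."""

    auc_mean: float
    auc_ci: tuple[float, float]
    per_repeat_aucs: np.ndarray
    sens: float
    spec: float
    seed: int


@dataclass
class SearchResult:
    """Ranked exhaustive-search outcome for one stratum/category pool."""

    ranked: list[tuple[LinearModel, CVEstimate | None]]
    search_space_size: int
    stratum: str = "all"
    category: str = "all"

    @property
    def best(self) -> LinearModel:
        return self.ranked[0][0]


SHRINKAGE = 1e-3


def _pooled_stats(X: np.ndarray, y: np.ndarray):
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    s0 = np.cov(X0, rowvar=False, ddof=1) if n0 > 1 else np.zeros((X.shape[1],) * 2)
    s1 = np.cov(X1, rowvar=False, ddof=1) if n1 > 1 else np.zeros((X.shape[1],) * 2)
    s0 = np.atleast_2d(s0)
    s1 = np.atleast_2d(s1)
    pooled = ((n0 - 1) * s0 + (n1 - 1) * s1) / max(n0 + n1 - 2, 1)
    return mu0, mu1, pooled


def fit_linear_discriminant(X, y, feature_names=None) -> LinearModel:
    """Fit the shrinkage LDA direction and Youden-optimal training cutoff."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _check_binary(np.asarray(y))
    if X.shape[0] <= X.shape[1] + 2:
        log.warning("few samples (%d) for %d features; shrinkage carries the fit",
                    X.shape[0], X.shape[1])
    k = X.shape[1]
    mu0, mu1, pooled = _pooled_stats(X, y)
    lam = SHRINKAGE * np.trace(pooled) / k
    if lam <= 0:
        lam = SHRINKAGE
    w = np.linalg.solve(pooled + lam * np.eye(k), mu1 - mu0)
    scores = X @ w
    j, cutoff, sens, spec = youden(scores, y)
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(k))
    return LinearModel(names, w, cutoff, auroc(scores, y), j, sens, spec)


def count_subsets(p: int, k: int) -> int:
    """Exact binomial coefficient C(p, k)."""
    if not (isinstance(p, int) and isinstance(k, int)) or p < 0 or not 0 <= k <= p:
        raise ValueError("need integers 0 <= k <= p")
    return math.comb(p, k)


# ---------------------------------------------------------------------------
# batched subset scoring


def _batch_j_auc(X: np.ndarray, y: np.ndarray, subsets: np.ndarray,
                 chunk: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Training J-index and AUROC of the shrinkage LDA for many subsets.

    ``subsets`` is an (m, k) integer index array.  Matches the single-model
    path (`fit_linear_discriminant` + `youden` + `auroc`) exactly.
    """
    y = _check_binary(y)
    n, p = X.shape
    m, k = subsets.shape
    n1 = int(y.sum())
    n0 = n - n1
    mu0, mu1, pooled = _pooled_stats(X, y)
    dmu = mu1 - mu0
    j_out = np.empty(m)
    auc_out = np.empty(m)
    is_pos = y == 1
    for start in range(0, m, chunk):
        idx = subsets[start:start + chunk]
        c = len(idx)
        sig = pooled[idx[:, :, None], idx[:, None, :]]
        lam = SHRINKAGE * np.einsum("mkk->m", sig) / k
        lam = np.maximum(lam, SHRINKAGE)
        sig = sig + lam[:, None, None] * np.eye(k)
        w = np.linalg.solve(sig, dmu[idx][..., None])[..., 0]
        scores = np.einsum("mnk,mk->mn", X[:, idx].transpose(1, 0, 2), w)
        ranks = stats.rankdata(scores, axis=1)
        auc_out[start:start + c] = (
            ranks[:, is_pos].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)
        # vectorized Youden J over cut positions between sorted scores
        order = np.argsort(scores, axis=1, kind="stable")
        s_sorted = np.take_along_axis(scores, order, axis=1)
        y_sorted = np.broadcast_to(y, (c, n))
        y_sorted = np.take_along_axis(y_sorted, order, axis=1)
        cum1 = np.cumsum(y_sorted == 1, axis=1)
        cum0 = np.cumsum(y_sorted == 0, axis=1)
        jmat = cum0 / n0 - cum1 / n1
        valid = np.diff(s_sorted, axis=1) > 0
        jmat = np.where(np.pad(valid, ((0, 0), (0, 1)), constant_values=True),
                        jmat, -np.inf)
        j_out[start:start + c] = np.maximum(jmat.max(axis=1), 0.0)
    return j_out, auc_out


def _rank_key(entry):
    j, auc, size, names = entry
    return (-j, -auc, size, names)


def exhaustive_search(table: pd.DataFrame, y, max_dim: int = 4,
                      feature_pool: list[str] | None = None,
                      top_m: int = 5, seed: int = 0,
                      cv_repeats: int = 200, train_frac: float = 0.8,
                      stratum: str = "all", category: str = "all",
                      run_cv: bool = True) -> SearchResult:
    """Exhaustively evaluate every feature subset of size 1..max_dim.

    Subsets are scored by training J-index/AUROC of the refit linear
    discriminant; the ``top_m`` per size are retained (ranked by J, mean
    AUROC, parsimony, names) and, when ``run_cv``, accompanied by a
    stratified repeated-hold-out CV estimate.
    """
    if max_dim > 4:
        raise ValueError("search dimension is limited to 4 features")
    pool = list(feature_pool) if feature_pool is not None else list(table.columns)
    if not pool:
        raise ValueError("empty feature pool")
    y = _check_binary(np.asarray(y))
    X = table[pool].to_numpy(float)
    p = len(pool)
    space = sum(count_subsets(p, k) for k in range(1, min(max_dim, p) + 1))
    if count_subsets(p, min(max_dim, p)) > SEARCH_SPACE_WARN:
        log.warning("search space C(%d, %d) exceeds the desk-scale guard", p,
                    max_dim)

    candidates: list[tuple[float, float, int, tuple[str, ...], np.ndarray]] = []
    for k in range(1, min(max_dim, p) + 1):
        subsets = np.fromiter(
            (i for comb in combinations(range(p), k) for i in comb),
            dtype=np.int64).reshape(-1, k)
        j, auc = _batch_j_auc(X, y, subsets)
        order = np.lexsort((np.arange(len(j)), -auc, -j))[:top_m]
        for i in order:
            names = tuple(pool[c] for c in subsets[i])
            candidates.append((float(j[i]), float(auc[i]), k, names, subsets[i]))
        log.info("size-%d search: %d subsets, best J=%.3f", k, len(subsets),
                 float(j.max()))

    candidates.sort(key=lambda e: (-e[0], -e[1], e[2], e[3]))
    ranked = []
    rng = np.random.default_rng(seed)
    for j, auc_val, k, names, idx in candidates:
        model = fit_linear_discriminant(X[:, idx], y, names)
        est = None
        if run_cv:
            est = holdout_cv(table, y, list(names), train_frac, cv_repeats,
                             int(rng.integers(0, 2**31 - 1)))
        ranked.append((model, est))
    return SearchResult(ranked, space, stratum, category)


def _stratified_split(y: np.ndarray, train_frac: float,
                      rng: np.random.Generator):
    train_idx, test_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise SingleClassError(
                f"class {cls} too small to stratify at train_frac={train_frac}")
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def holdout_cv(table: pd.DataFrame, y, features: list[str],
               train_frac: float = 0.8, repeats: int = 200,
               seed: int = 0) -> CVEstimate:
    """Stratified repeated hold-out AUROC for one feature subset.

    Per repeat: fit on a stratified ``train_frac`` split, evaluate the
    AUROC (and sens/spec at the frozen training cutoff) on the held-out
    fraction.  The CI is the empirical 2.5/97.5 percentile band over
    repeats.
    """
    y = _check_binary(np.asarray(y))
    X = table[list(features)].to_numpy(float)
    rng = np.random.default_rng(seed)
    aucs = np.empty(repeats)
    sens = np.empty(repeats)
    spec = np.empty(repeats)
    for r in range(repeats):
        tr, te = _stratified_split(y, train_frac, rng)
        model = fit_linear_discriminant(X[tr], y[tr])
        s = X[te] @ model.weights
        aucs[r] = auroc(s, y[te])
        pos = s >= model.cutoff
        yt = y[te]
        sens[r] = (pos & (yt == 1)).sum() / max((yt == 1).sum(), 1)
        spec[r] = (~pos & (yt == 0)).sum() / max((yt == 0).sum(), 1)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return CVEstimate(float(aucs.mean()), (float(lo), float(hi)), aucs,
                      float(sens.mean()), float(spec.mean()), seed)


def evaluate_on_test(model: LinearModel, test_table: pd.DataFrame, y_test,
                     repeats: int = 1000, seed: int = 0) -> CVEstimate:
    """Frozen-model AUROC on an independent test set, bootstrap CI.

    Sens/spec use the training Youden cutoff applied unchanged to the test
    scores.
    """
    y = _check_binary(np.asarray(y_test))
    s = model.score(test_table)
    point = auroc(s, y)
    pos = s >= model.cutoff
    sens = float((pos & (y == 1)).sum() / (y == 1).sum())
    spec = float((~pos & (y == 0)).sum() / (y == 0).sum())
    rng = np.random.default_rng(seed)
    boot = np.empty(repeats)
    n = len(y)
    for r in range(repeats):
        idx = rng.integers(0, n, n)
        while len(np.unique(y[idx])) < 2:
            idx = rng.integers(0, n, n)
        boot[r] = auroc(s[idx], y[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)
    return CVEstimate(point, (float(lo), float(hi)), boot, sens, spec, seed)


def augment_clinical(table: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Append z-scored/0-1-coded clinical covariates as candidate features.

    Continuous covariates (age, pack_years) are z-scored; sex and
    smoke_status are coded {0, 1} (accepting M/F and current/former
    strings).  Missing values raise; no imputation is attempted.
    """
    cov = clinical.loc[table.index]
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"missing clinical covariate values in: {bad}")
    out = table.copy()
    for name in ("age", "pack_years"):
        if name in cov:
            x = cov[name].to_numpy(float)
            sd = x.std()
            out[f"clin_{name}"] = (x - x.mean()) / (sd if sd > 0 else 1.0)
    codes = {"M": 1, "F": 0, "male": 1, "female": 0,
             "current": 1, "former": 0}
    for name in ("sex", "smoke_status"):
        if name in cov:
            col = cov[name]
            if col.dtype == object:
                col = col.map(lambda v: codes.get(str(v), v))
            out[f"clin_{name}"] = col.astype(float)
    return out


def stratify_by_size(table: pd.DataFrame, longest_diameters,
                     size_range: str = "all") -> pd.DataFrame:
    """Subset rows by nodule size stratum measured as longest diameter (mm).

    ``R1`` is the indeterminate range [4, 12] mm (12.0 inclusive), ``R2``
    is (12, 30]; nodules outside [4, 30] are excluded from both strata but
    kept under ``all``.
    """
    d = pd.Series(np.asarray(longest_diameters, dtype=float), index=table.index)
    if size_range == "all":
        return table.copy()
    if size_range == "R1":
        keep = (d >= 4.0) & (d <= 12.0)
    elif size_range == "R2":
        keep = (d > 12.0) & (d <= 30.0)
    else:
        raise ValueError(f"unknown size range {size_range!r}")
    return table[keep.to_numpy()].copy()


def kernel_sensitivity(features: list[str], table_a: pd.DataFrame,
                       table_b: pd.DataFrame, y,
                       families: pd.Series | None = None) -> pd.DataFrame:
    """Cross-kernel AUROC stability of univariate feature models.

    For each feature, a linear model trained on kernel-A values is scored
    on kernel-B values and vice versa; ``delta_auc`` is the absolute
    difference of the two transfer AUROCs.  The summary fractions of
    features below 5% and 10% variability are stored in
    ``DataFrame.attrs['fractions']`` (per family when ``families`` given).
    """
    if not table_a.index.equals(table_b.index):
        raise ValueError("kernel tables must cover the same subjects")
    y = _check_binary(np.asarray(y))
    rows = []
    for name in features:
        m_a = fit_linear_discriminant(table_a[[name]].to_numpy(float), y, (name,))
        m_b = fit_linear_discriminant(table_b[[name]].to_numpy(float), y, (name,))
        auc_ab = auroc(table_b[[name]].to_numpy(float) @ m_a.weights, y)
        auc_ba = auroc(table_a[[name]].to_numpy(float) @ m_b.weights, y)
        rows.append({"feature": name, "auc_train_a_test_b": auc_ab,
                     "auc_train_b_test_a": auc_ba,
                     "delta_auc": abs(auc_ab - auc_ba)})
    out = pd.DataFrame(rows).set_index("feature")
    if families is not None:
        out["family"] = families.reindex(out.index)
    out.attrs["fractions"] = variability_fractions(
        out["delta_auc"], out["family"] if families is not None else None)
    return out


def variability_fractions(delta_auc: pd.Series,
                          families: pd.Series | None = None) -> dict:
    """Fraction of features with |dAUC| below 0.05 and 0.10, per family."""
    d = pd.Series(delta_auc)

    def frac(sub):
        return {"below_5pct": float((sub < 0.05).mean()),
                "below_10pct": float((sub < 0.10).mean())}

    out = {"overall": frac(d)}
    if families is not None:
        for fam, sub in d.groupby(pd.Series(families)):
            out[str(fam)] = frac(sub)
    return out
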