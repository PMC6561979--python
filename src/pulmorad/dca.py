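"""Decision-curve analysis: net benefit over threshold probabilities.

Net benefit at threshold probability ``p_t`` weighs true against false
positives by the odds a patient would accept at that threshold:
``NB = TP/n - (FP/n) * p_t / (1 - p_t)``.  A model is compared against the
two reference policies (treat all, treat none) and optional comparator
models such as the longest-diameter baseline.  Discriminant scores are
mapped to risk probabilities by one-dimensional logistic calibration, a
monotone transform that leaves the AUROC unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .discriminant import _check_binary

log = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.01, 0.601, 0.01), 4)


def calibrate_scores(scores, y) -> np.ndarray:
    """Map discriminant scores to risk probabilities in (0, 1).

    Fits a one-dimensional maximum-likelihood logistic regression of the
    label on the score.  If the optimizer fails to converge, falls back to
    min-max scaling of the scores (with a logged warning); either way the
    map is monotone increasing in the score.
    """
    y = _check_binary(np.asarray(y))
    s = np.asarray(scores, dtype=float).reshape(-1, 1)
    try:
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        lr.fit(s, y)
        if lr.n_iter_[0] >= 2000:
            raise RuntimeError("logistic calibration did not converge")
        p = lr.predict_proba(s)[:, 1]
        if lr.coef_[0, 0] < 0:
            # degenerate anti-concordant fit; keep monotone-increasing contract
            raise RuntimeError("non-monotone calibration")
    except (RuntimeError, FloatingPointError) as exc:
        log.warning("logistic calibration failed (%s); min-max fallback", exc)
        lo, hi = s.min(), s.max()
        span = hi - lo if hi > lo else 1.0
        p = 0.001 + 0.998 * (s.ravel() - lo) / span
    return np.clip(p, 1e-9, 1 - 1e-9)


def net_benefit(risks, y, p_t: float) -> float:
    """Net benefit of treating at risk >= ``p_t``; ``p_t`` must be in (0, 1)."""
    if not 0 < p_t < 1:
        raise ValueError("threshold probability must lie strictly in (0, 1)")
    y = np.asarray(y).astype(int)
    r = np.asarray(risks, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risks must lie in [0, 1]")
    n = len(y)
    treat = r >= p_t
    tp = int((treat & (y == 1)).sum())
    fp = int((treat & (y == 0)).sum())
    return float(tp / n - (fp / n) * p_t / (1 - p_t))


@dataclass
class DecisionCurve:
    """Net-benefit curves for a model and its comparators."""

    thresholds: np.ndarray
    curves: pd.DataFrame  # one column per model, aligned to thresholds
    nb_all: np.ndarray
    nb_none: np.ndarray
    prevalence: float
    crossing_threshold: float | None  # lowest p_t where the first model wins

    def frame(self) -> pd.DataFrame:
        out = self.curves.copy()
        out.insert(0, "threshold", self.thresholds)
        out["treat_all"] = self.nb_all
        out["treat_none"] = self.nb_none
        return out


def decision_curve(risks_by_model: dict[str, np.ndarray], y,
                   grid=None) -> DecisionCurve:
    """Net benefit of each model plus treat-all/treat-none on a grid.

    The first entry of ``risks_by_model`` is the model of interest; the
    reported ``crossing_threshold`` is the lowest grid point at which its
    net benefit strictly exceeds every comparator (other models and both
    reference policies), or None if that never happens.
    """
    y = _check_binary(np.asarray(y))
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    n = len(y)
    pi = float(y.mean())
    names = list(risks_by_model)
    lengths = {len(np.asarray(r)) for r in risks_by_model.values()}
    if lengths != {n}:
        raise ValueError("all models must cover the same subjects as y")
    curves = pd.DataFrame(
        {name: [net_benefit(risks_by_model[name], y, t) for t in grid]
         for name in names})
    nb_all = pi - (1 - pi) * grid / (1 - grid)
    nb_none = np.zeros_like(grid)

    crossing = None
    if names:
        primary = curves[names[0]].to_numpy()
        rivals = [curves[m].to_numpy() for m in names[1:]] + [nb_all, nb_none]
        wins = np.all([primary > rv for rv in rivals], axis=0)
        if wins.any():
            crossing = float(grid[int(np.argmax(wins))])
    return DecisionCurve(grid, curves, nb_all, nb_none, pi, crossing)


def plot_decision_curve(curve: DecisionCurve, path=None, title=None):
    """Plot the decision curve; writes to ``path`` when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name in curve.curves.columns:
        ax.plot(curve.thresholds, curve.curves[name], label=name)
    ax.plot(curve.thresholds, curve.nb_all, "k--", label="treat all")
    ax.plot(curve.thresholds, curve.nb_none, "k:", label="treat none")
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.05, ax.get_ylim()[0]))
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
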