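"""Decide which and how many regulators form the next layer.

Three selection modes are provided:

* ``top_k`` -- keep the k regulators with the highest interference counts
  (deterministic tie-break: larger summed |D| over interfered pairs, then
  lexicographically smaller identifier);
* ``top_percent`` -- keep a fixed percentage of the tallied regulators;
* ``wscca`` -- weighted sparse canonical correlation analysis.  WSCCA finds
  unit vectors u (over bottom-layer genes) and v (over candidates) that
  maximize

      u' X' Y v  -  lambda * sum_i W_i |v_i|,    ||u||_2 = ||v||_2 = 1,

  where W_i = max_count - count_i penalizes weak interferers: the regulators
  with the most interference have W_i = 0 and are never thresholded out.
  The biconvex problem is solved by alternating exact updates -- u is the
  normalized image X'Yv, v is the weighted soft-thresholding of Y'Xu followed
  by l2 normalization -- and lambda is chosen by cross-validated held-out
  canonical correlation.  Regulators with a nonzero v loading are kept.
  Scaling the chosen lambda up (``lam_scale=2``) keeps only the most
  persistent regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LambdaTooLargeError
from .triplet_engine import InterferenceTally

logger = logging.getLogger(__name__)

__all__ = ["WsccaModel", "select_top_k", "select_top_percent", "wscca_fit", "wscca_select"]


@dataclass
class WsccaModel:
    """Converged WSCCA solution for one layer."""

    u: np.ndarray
    v: np.ndarray
    W: np.ndarray
    lam: float
    objective_trace: list[float] = field(default_factory=list)
    candidate_ids: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        """Candidate identifiers with a nonzero v loading."""
        return [cid for cid, vi in zip(self.candidate_ids, self.v) if vi != 0.0]


def _ranked(tallies: Sequence[InterferenceTally]) -> list[InterferenceTally]:
    return sorted(tallies, key=lambda t: (-t.count, -t.total_abs_d, t.z_id))


def select_top_k(tallies: Sequence[InterferenceTally], k: int) -> list[str]:
    """The k regulators with the highest interference counts.  Regulators
    with zero counts never appear, so fewer than k may be returned."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    ranked = [t for t in _ranked(tallies) if t.count > 0]
    return [t.z_id for t in ranked[:k]]


def select_top_percent(tallies: Sequence[InterferenceTally], percent: float) -> list[str]:
    """Keep ``percent`` % (of the tallied regulators), at least one."""
    if not 0.0 < percent <= 100.0:
        raise ConfigurationError(f"percent must be in (0, 100], got {percent}")
    nonzero = [t for t in _ranked(tallies) if t.count > 0]
    if not nonzero:
        return []
    k = max(1, int(np.ceil(percent / 100.0 * len(nonzero))))
    return [t.z_id for t in nonzero[:k]]


def _standardize(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a = a - a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    sd[sd == 0.0] = 1.0
    return a / sd


def _soft(a: np.ndarray, thresh: np.ndarray) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - thresh, 0.0)


def wscca_fit(
    X: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray,
    lam: float,
    candidate_ids: Sequence[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> WsccaModel:
    """Alternating maximization of the weighted sparse CCA objective.

    ``X`` (n x p) and ``Y`` (n x q) are sample-by-gene matrices (standardized
    internally, which is idempotent on pre-scaled input); ``W`` >= 0 has
    length q.  With ``lam == 0`` or ``W == 0`` the solution is the leading
    singular-vector pair of X'Y.  Raises :class:`LambdaTooLargeError` when
    soft-thresholding zeroes all of v.
    """
    X = _standardize(X)
    Y = _standardize(Y)
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ConfigurationError("weights W must be non-negative")
    if lam < 0:
        raise ConfigurationError("lambda must be >= 0")
    M = X.T @ Y                      # p x q
    if not np.any(M):
        raise ConfigurationError("X'Y is the zero matrix")

    # deterministic init: leading right singular vector of M
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    thresh = lam * W
    trace: list[float] = []
    for _ in range(max_iter):
        Mv = M @ v
        nu = np.linalg.norm(Mv)
        if nu == 0.0:
            raise ConfigurationError("degenerate u-update: X'Yv = 0")
        u = Mv / nu
        v_new = _soft(M.T @ u, thresh)
        nv = np.linalg.norm(v_new)
        if nv == 0.0:
            raise LambdaTooLargeError(f"lambda={lam:g} zeroed every v coordinate")
        v_new /= nv
        trace.append(float(u @ M @ v_new - np.sum(thresh * np.abs(v_new))))
        delta = np.linalg.norm(v_new - v)
        v = v_new
        if delta < tol:
            break
    ids = list(candidate_ids) if candidate_ids is not None else [
        f"c{i}" for i in range(Y.shape[1])
    ]
    return WsccaModel(u=u, v=v, W=W, lam=float(lam), objective_trace=trace,
                      candidate_ids=ids)


def _weights_from_tallies(
    tallies: Sequence[InterferenceTally], candidate_ids: Sequence[str]
) -> np.ndarray:
    counts = {t.z_id: t.count for t in tallies}
    c = np.array([counts.get(cid, 0) for cid in candidate_ids], dtype=float)
    return c.max() - c


def _cv_score(X, Y, W, lam, folds, order) -> float:
    """Mean held-out canonical correlation across folds; -inf when lambda
    kills v on any training fold."""
    scores = []
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(order, test)
        try:
            model = wscca_fit(X[train], Y[train], W, lam)
        except LambdaTooLargeError:
            return -np.inf
        xt = _standardize(X[test]) @ model.u
        yt = _standardize(Y[test]) @ model.v
        if xt.std() == 0.0 or yt.std() == 0.0:
            return -np.inf
        scores.append(abs(np.corrcoef(xt, yt)[0, 1]))
    return float(np.mean(scores))


def wscca_select(
    X,
    Y,
    tallies: Sequence[InterferenceTally],
    lam_grid: Sequence[float] | None = None,
    folds: int = 5,
    lam_scale: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Choose lambda by cross-validation and return the selected regulators.

    ``X`` and ``Y`` may be genes x samples DataFrames (transposed internally)
    or sample-by-gene arrays; ``Y``'s candidates are restricted to the
    tallied regulators (those with at least one interference).  The final
    model is fit at ``lam * lam_scale``; doubling lambda (``lam_scale=2``)
    trims the layer to the most persistent regulators.
    """
    if folds < 2:
        raise ConfigurationError(f"folds must be >= 2, got {folds}")
    if lam_scale < 1.0:
        raise ConfigurationError(f"lam_scale must be >= 1, got {lam_scale}")
    if not tallies:
        return []
    tallied_ids = [t.z_id for t in _ranked(tallies) if t.count > 0]
    if not tallied_ids:
        return []

    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float).T
    if isinstance(Y, pd.DataFrame):
        # restrict the candidate matrix to the tallied regulators
        ids = tallied_ids
        Y = Y.loc[ids].to_numpy(float).T
    else:
        Y = np.asarray(Y, dtype=float)
        ids = [f"c{i}" for i in range(Y.shape[1])]   # positional identifiers
    X = np.asarray(X, dtype=float)
    if X.shape[0] < folds:
        raise ConfigurationError(
            f"{X.shape[0]} samples cannot be split into {folds} folds"
        )
    W = _weights_from_tallies(tallies, ids)

    if lam_grid is None:
        base = wscca_fit(X, Y, W, 0.0, candidate_ids=tallied_ids)
        grad = np.abs(_standardize(Y).T @ (_standardize(X) @ base.u))
        lam_max = float(np.max(grad / np.maximum(W, 1e-8)))
        lam_grid = np.geomspace(1e-3, max(lam_max, 1e-3), 20)

    # one seeded fold assignment shared by every lambda
    order = np.random.default_rng(seed).permutation(X.shape[0])
    scores = [_cv_score(X, Y, W, lam, folds, order) for lam in lam_grid]
    best = int(np.argmax(scores))
    lam = float(lam_grid[best]) * lam_scale
    logger.info("wscca: cv chose lambda=%.4g (score %.4f), fitting at %.4g",
                lam_grid[best], scores[best], lam)

    # walk lambda down if the scaled value kills every coordinate
    while True:
        try:
            model = wscca_fit(X, Y, W, lam, candidate_ids=ids)
            break
        except LambdaTooLargeError:
            lam /= 2.0
            if lam < 1e-12:
                model = wscca_fit(X, Y, W, 0.0, candidate_ids=ids)
                break
    return model.selected
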