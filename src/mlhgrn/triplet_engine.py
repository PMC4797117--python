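"""Enumerate and evaluate (gene-pair, regulator) triplets for one layer.

Every unordered pair (x, y) of current bottom-layer genes is combined with
every candidate regulator z.  Per triplet the engine computes the Spearman
correlation r_xy (p-value p1), the first-order partial correlation r_xy|z
(p-value p2), and, when both are significant, the delta-method difference
test (p-value p3).  The decision table over (p1, p2, p3) yields one of four
circumstances:

    1. r_xy significant, r_xy|z not        -> z interferes
    2. both significant                    -> z interferes iff p3 significant
    3. r_xy not significant, r_xy|z is     -> z interferes
    4. neither significant                 -> triplet discarded

Interference p-values are then corrected for multiple testing jointly across
all interfering triplets of the layer, and interference counts are tallied
per regulator.  Evaluation is order-independent: triplets are generated in
canonical (sorted-identifier) order and share no state apart from the final,
order-invariant multiplicity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import correlation_stats as cs
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: accepted spellings of correction methods -> statsmodels name (or None)
_CORRECTION_METHODS = {
    "bh": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "benjamini-hochberg": "fdr_bh",
    "bonferroni": "bonferroni",
    "none": None,
}

__all__ = [
    "TripletResult",
    "InterferenceTally",
    "classify_triplet",
    "evaluate_triplet",
    "evaluate_layer",
    "correct_pvalues",
    "tally_interference",
]


@dataclass(frozen=True)
class TripletResult:
    """Outcome of one (x, y, z) interference evaluation.

    ``p3`` is present only when both p1 and p2 are significant (circumstance
    2); ``p_adjusted`` is filled by :func:`correct_pvalues`.
    """

    x_id: str
    y_id: str
    z_id: str
    r_xy: float
    r_xy_given_z: float
    p1: float
    p2: float
    p3: float | None
    circumstance: int
    interferes: bool
    p_adjusted: float | None = None

    @property
    def d(self) -> float:
        """Correlation difference D = r_xy - r_xy|z."""
        return self.r_xy - self.r_xy_given_z

    @property
    def operative_p(self) -> float:
        """The p-value that established (or refuted) interference: p1 in
        circumstance 1, p3 in circumstance 2, p2 in circumstance 3."""
        if self.circumstance == 2:
            assert self.p3 is not None
            return self.p3
        return self.p1 if self.circumstance == 1 else self.p2


@dataclass
class InterferenceTally:
    """Per-regulator count of significantly interfered gene pairs."""

    z_id: str
    count: int
    pairs: list[tuple[str, str]] = field(default_factory=list)
    total_abs_d: float = 0.0   # tie-break statistic for ranking


def classify_triplet(
    p1: float,
    p2: float,
    p3: float | None,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    alpha3: float = 0.05,
) -> tuple[int, bool]:
    """Apply the four-circumstance decision table; returns
    ``(circumstance, interferes)``.  ``p3`` is required exactly when both p1
    and p2 are significant."""
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p!r} is not a p-value")
    sig1 = p1 < alpha1
    sig2 = p2 < alpha2
    if sig1 and sig2:
        if p3 is None:
            raise ValueError("p3 is required when both p1 and p2 are significant")
        return 2, bool(p3 < alpha3)
    if sig1:
        return 1, True
    if sig2:
        return 3, True
    return 4, False


def evaluate_triplet(
    x,
    y,
    z,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    alpha3: float = 0.05,
    x_id: str = "x",
    y_id: str = "y",
    z_id: str = "z",
) -> TripletResult:
    """Evaluate a single triplet from raw expression vectors."""
    n = len(np.asarray(x))
    r_xy = cs.spearman_correlation(x, y)
    r_zy = cs.spearman_correlation(z, y)
    r_zx = cs.spearman_correlation(z, x)
    out = cs.batch_difference_test(
        np.asarray([r_xy]), np.asarray([r_zy]), np.asarray([r_zx]), n
    )
    pcor = float(out["pcor"][0])
    p1 = cs.correlation_pvalue(r_xy, n)
    p2 = cs.correlation_pvalue(pcor, n, conditioned_on=1)
    sig_both = (p1 < alpha1) and (p2 < alpha2)
    p3 = float(out["p3"][0]) if sig_both else None
    circ, interferes = classify_triplet(p1, p2, p3, alpha1, alpha2, alpha3)
    return TripletResult(x_id, y_id, z_id, r_xy, pcor, p1, p2, p3, circ, interferes)


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix over rows (genes) of a genes x samples
    array, midrank ties."""
    ranks = stats.rankdata(values, axis=1)
    return np.corrcoef(ranks)


def evaluate_layer(
    bottom: pd.DataFrame,
    candidates: pd.DataFrame,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    alpha3: float = 0.05,
    keep_discarded: bool = False,
) -> list[TripletResult]:
    """Evaluate all C(m, 2) * q triplets of a layer.

    ``bottom`` and ``candidates`` are genes x samples DataFrames with
    disjoint, unique gene identifiers and identical sample columns.  Constant
    genes are skipped with a logged warning.  Triplets of circumstance 4
    ("discard") are omitted unless ``keep_discarded``.

    The computation is vectorized: one Spearman matrix over all genes, then
    array evaluation of every triplet statistic.
    """
    overlap = sorted(set(bottom.index) & set(candidates.index))
    if overlap:
        raise InputError(f"gene ids present in both inputs: {overlap}")
    if bottom.shape[1] != candidates.shape[1]:
        raise InputError(
            f"sample count mismatch: {bottom.shape[1]} vs {candidates.shape[1]}"
        )
    n = bottom.shape[1]

    bottom = bottom.sort_index()
    candidates = candidates.sort_index()
    for name, frame in (("bottom", bottom), ("candidates", candidates)):
        const = frame.index[frame.nunique(axis=1) <= 1]
        if len(const):
            logger.warning(
                "%s: dropping %d constant gene(s): %s", name, len(const), list(const)
            )
            frame.drop(index=const, inplace=True)

    m, q = bottom.shape[0], candidates.shape[0]
    if m < 2 or q == 0:
        return []

    corr = _spearman_matrix(np.vstack([bottom.to_numpy(float), candidates.to_numpy(float)]))
    r_bb = corr[:m, :m]
    r_bc = corr[:m, m:]          # bottom x candidate

    pair_idx = np.array(list(combinations(range(m), 2)))   # (P, 2), i < j
    i_idx, j_idx = pair_idx[:, 0], pair_idx[:, 1]
    r_xy = r_bb[i_idx, j_idx]                               # (P,)
    p1 = cs.correlation_pvalue(r_xy, n)

    # broadcast pairs against candidates: shape (P, q)
    r_zx = r_bc[i_idx, :]
    r_zy = r_bc[j_idx, :]
    out = cs.batch_difference_test(r_xy[:, None], r_zy, r_zx, n)
    pcor = out["pcor"]
    p2 = cs.correlation_pvalue(pcor, n, conditioned_on=1)
    p3 = out["p3"]

    sig1 = p1[:, None] < alpha1
    sig2 = p2 < alpha2
    circ = np.where(
        sig1 & sig2, 2, np.where(sig1, 1, np.where(sig2, 3, 4))
    )
    interferes = (circ == 1) | (circ == 3) | ((circ == 2) & (p3 < alpha3))

    bottom_ids = list(bottom.index)
    cand_ids = list(candidates.index)
    results: list[TripletResult] = []
    p1_b = np.broadcast_to(p1[:, None], circ.shape)
    r_xy_b = np.broadcast_to(r_xy[:, None], circ.shape)
    for pi in range(circ.shape[0]):
        x_id, y_id = bottom_ids[i_idx[pi]], bottom_ids[j_idx[pi]]
        for zi in range(q):
            c = int(circ[pi, zi])
            if c == 4 and not keep_discarded:
                continue
            results.append(
                TripletResult(
                    x_id,
                    y_id,
                    cand_ids[zi],
                    float(r_xy_b[pi, zi]),
                    float(pcor[pi, zi]),
                    float(p1_b[pi, zi]),
                    float(p2[pi, zi]),
                    float(p3[pi, zi]) if c == 2 else None,
                    c,
                    bool(interferes[pi, zi]),
                )
            )
    logger.info(
        "evaluated %d triplets (%d pairs x %d candidates), retained %d",
        circ.size, circ.shape[0], q, len(results),
    )
    return results


def correct_pvalues(
    results: Sequence[TripletResult],
    method: str = "fdr_bh",
    alpha: float = 0.05,
    mode: str = "operative",
) -> list[TripletResult]:
    """Correct interference p-values for multiple testing across a layer.

    Per the decision-table semantics each interfering triplet contributes its
    operative p-value (``mode="operative"``: p1 / p3 / p2 for circumstances
    1 / 2 / 3); ``mode="p3_only"`` corrects only circumstance-2 triplets and
    leaves circumstances 1 and 3 standing on their already-significant test.
    ``interferes`` is recomputed as ``p_adjusted < alpha``.  Non-interfering
    triplets pass through unchanged.
    """
    key = method.lower()
    if key not in _CORRECTION_METHODS:
        raise ConfigurationError(
            f"unknown correction method {method!r}; choose from "
            f"{sorted(_CORRECTION_METHODS)}"
        )
    if mode not in ("operative", "p3_only"):
        raise ConfigurationError(f"unknown correction mode {mode!r}")
    sm_method = _CORRECTION_METHODS[key]

    corrected = list(results)
    idx = [
        i
        for i, t in enumerate(corrected)
        if t.interferes and not (mode == "p3_only" and t.circumstance != 2)
    ]
    if not idx:
        return corrected
    raw = np.array([corrected[i].operative_p for i in idx])
    if sm_method is None:
        adj = raw
    else:
        adj = multipletests(raw, alpha=alpha, method=sm_method)[1]
    for i, p_adj in zip(idx, adj):
        t = corrected[i]
        corrected[i] = replace(t, p_adjusted=float(p_adj), interferes=bool(p_adj < alpha))
    return corrected


def tally_interference(results: Sequence[TripletResult]) -> list[InterferenceTally]:
    """Count interfered gene pairs per regulator (regulators with at least
    one interference only), sorted by identifier."""
    tallies: dict[str, InterferenceTally] = {}
    for t in results:
        if not t.interferes:
            continue
        tally = tallies.setdefault(t.z_id, InterferenceTally(t.z_id, 0))
        tally.count += 1
        tally.pairs.append((t.x_id, t.y_id))
        tally.total_abs_d += abs(t.d)
    return [tallies[z] for z in sorted(tallies)]
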