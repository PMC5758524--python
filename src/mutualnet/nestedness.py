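"""NODF nestedness and its significance under the Ce null model.

NODF (nestedness metric based on overlap and decreasing fill) scores every
pair of rows and every pair of columns of a binary incidence matrix.  A
pair contributes the percentage of the sparser member's links that are
shared with the denser member, but only when the fills strictly decrease —
pairs with equal marginal totals contribute zero.  The network value is the
mean over all C(R,2) + C(C,2) pair contributions, ranging from 0
(non-nested) to 100 (perfectly nested).  Significance is assessed against
an ensemble of Ce-null matrices, whose cell occupancy probability is the
mean of the cell's row and column fill proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nulls import CeProbabilityMatrix, as_rng
from .core import LayerMatrix

__all__ = ["NodfResult", "paired_overlap", "nodf", "nodf_components", "nodf_significance"]


@dataclass
class NodfResult:
    nodf: float
    nodf_rows: float
    nodf_cols: float
    null_mean: float
    null_sd: float
    z: float | None
    p_value: float
    n_null: int
    seed: object


def _as_binary(matrix) -> np.ndarray:
    if isinstance(matrix, LayerMatrix):
        matrix = matrix.presence
    m = np.asarray(matrix)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("matrix must be binary")
    return m.astype(np.int64)


def paired_overlap(matrix, axis: str, i: int, j: int) -> float:
    """Nestedness contribution (percent) of one row or column pair.

    The denser member must strictly exceed the sparser one in marginal
    total (the decreasing-fill rule): equal totals, or an empty sparser
    member, contribute 0.  Otherwise the contribution is 100 x (shared
    links) / (sparser member's links).
    """
    m = _as_binary(matrix)
    if axis == "cols":
        m = m.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    if i == j:
        raise ValueError("indices must differ")
    a, b = m[i], m[j]  # raises IndexError on out-of-range indices
    da, db = int(a.sum()), int(b.sum())
    if da == db:
        return 0.0
    if da < db:
        a, b, da, db = b, a, db, da
    if db == 0:
        return 0.0
    return 100.0 * int((a & b).sum()) / db


def nodf_components(matrix) -> tuple[float, float, float]:
    """(pooled NODF, row-pair mean, column-pair mean).

    Vectorized over all pairs: shared-link counts come from the Gram
    matrices ``M M^T`` and ``M^T M``; a pair's contribution is
    100 x shared / min(deg) when the degrees differ and the smaller one is
    positive, else 0.  Invariant to row/column permutations.
    """
    m = _as_binary(matrix)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")

    def _pair_sum(mm: np.ndarray) -> tuple[float, int]:
        deg = mm.sum(axis=1)
        shared = mm @ mm.T
        lo = np.minimum(deg[:, None], deg[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(
                (deg[:, None] != deg[None, :]) & (lo > 0), 100.0 * shared / lo, 0.0
            )
        iu = np.triu_indices(len(deg), k=1)
        return float(contrib[iu].sum()), len(iu[0])

    rsum, rn = _pair_sum(m)
    csum, cn = _pair_sum(m.T)
    pooled = (rsum + csum) / (rn + cn)
    return pooled, rsum / rn if rn else 0.0, csum / cn if cn else 0.0


def nodf(matrix) -> float:
    """Pooled NODF of a binary matrix, in [0, 100]."""
    return nodf_components(matrix)[0]


def nodf_significance(matrix, n_null: int = 1000, rng=None) -> NodfResult:
    """NODF with a one-tailed Ce-ensemble probability of higher nestedness.

    ``p = #{null NODF >= observed} / n_null`` (ties toward the tail);
    ``z = (observed - null mean) / null sd``, reported as ``None`` when the
    null ensemble is degenerate (sd = 0).
    """
    rng = as_rng(rng)
    m = _as_binary(matrix)
    obs, obs_rows, obs_cols = nodf_components(m)
    mm, nn = m.shape
    rowfill = m.sum(axis=1) / nn
    colfill = m.sum(axis=0) / mm
    probs = CeProbabilityMatrix((rowfill[:, None] + colfill[None, :]) / 2.0)
    null = np.empty(n_null)
    for r in range(n_null):
        null[r] = nodf_components((rng.random(m.shape) < probs.probs).astype(np.int64))[0]
    sd = float(np.std(null, ddof=1))
    z = (obs - float(np.mean(null))) / sd if sd > 0 else None
    p = float(np.sum(null >= obs) / n_null)
    return NodfResult(
        obs, obs_rows, obs_cols, float(np.mean(null)), sd, z, p, n_null, None
    )
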