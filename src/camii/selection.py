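"""Morphology embedding, diverse colony selection and strategy evaluation.

Colonies are embedded by PCA of their z-scored morphology features, and the
picking set is built greedily by farthest-first traversal (max-min dispersion,
a 2-approximation of the optimal max-min subset): start from the globally
most distant pair, then repeatedly add the colony farthest from the chosen
set. Picking strategies are compared by the accumulation of unique taxa along
the pick order, summarised as area under the curve with a paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import cdist

from .imaging import MORPHOLOGY_FEATURES

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """PCA scores of z-scored features, with the scaling used to build them."""

    scores: np.ndarray  # (n, k)
    explained_variance_fraction: np.ndarray  # (k,), non-increasing
    components: np.ndarray  # (k, n_features) loadings, rows are components
    feature_means: np.ndarray
    feature_sds: np.ndarray
    feature_names: list[str]
    ids: list[str]


def embed_morphology(
    table: pd.DataFrame, feature_columns: list[str] | None = None, id_column: str = "colony_id"
) -> Embedding:
    """Z-score the feature columns and project onto principal components.

    PCA is by eigendecomposition of the covariance matrix; all components are
    retained. Zero-variance columns are dropped with a logged warning.
    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making the embedding deterministic.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 colonies to embed")
    feats = feature_columns or [c for c in MORPHOLOGY_FEATURES if c in table.columns]
    X = table[feats].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite values")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [f for f, k in zip(feats, keep) if not k]
        logger.warning("dropping zero-variance feature columns: %s", dropped)
    feats = [f for f, k in zip(feats, keep) if k]
    X = (X[:, keep] - means[keep]) / sds[keep]

    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):  # deterministic sign
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = X @ eigvecs
    total = eigvals.sum()
    evf = eigvals / total if total > 0 else np.zeros_like(eigvals)

    if id_column in table.columns:
        ids = table[id_column].astype(str).tolist()
    else:
        ids = [str(i) for i in table.index]
    return Embedding(
        scores=scores,
        explained_variance_fraction=evf,
        components=eigvecs.T,
        feature_means=means[keep],
        feature_sds=sds[keep],
        feature_names=feats,
        ids=ids,
    )


def select_diverse(
    embedding: Embedding | np.ndarray,
    k: int,
    ids: list[str] | None = None,
    n_components: int | None = None,
) -> list[str]:
    """Greedy farthest-first pick of ``k`` morphologically distinct colonies.

    Initialized with the two points at maximum pairwise Euclidean distance
    (the diameter pair), then each step adds the point maximizing its minimum
    distance to the chosen set. All ties break toward the lowest colony id.
    Returns colony ids in pick order.
    """
    if isinstance(embedding, Embedding):
        pts = embedding.scores
        ids = ids or embedding.ids
    else:
        pts = np.asarray(embedding, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        ids = ids or [str(i) for i in range(len(pts))]
    if n_components is not None:
        pts = pts[:, :n_components]
    n = len(pts)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    ids = [str(i) for i in ids]

    dmat = cdist(pts, pts)
    # diameter pair, ties by lexicographically smallest sorted id pair
    best = None
    for i in range(n):
        for j in range(i + 1, n):
            key = (-dmat[i, j], *sorted((ids[i], ids[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
    if n == 1:
        return [ids[0]]
    _, i0, j0 = best
    first, second = sorted((i0, j0), key=lambda t: ids[t])
    chosen = [first]
    if k >= 2:
        chosen.append(second)
    mind = np.minimum(dmat[first], dmat[second]) if k >= 2 else dmat[first].copy()
    in_set = np.zeros(n, dtype=bool)
    in_set[chosen] = True
    while len(chosen) < k:
        cand = None
        for i in range(n):
            if in_set[i]:
                continue
            key = (-mind[i], ids[i])
            if cand is None or key < cand[0]:
                cand = (key, i)
        _, nxt = cand
        chosen.append(nxt)
        in_set[nxt] = True
        mind = np.minimum(mind, dmat[nxt])
    return [ids[i] for i in chosen]


def random_order(ids: list[str], seed: int) -> list[str]:
    """Seeded uniform-random pick order (the random-picking baseline)."""
    rng = np.random.default_rng(seed)
    ids = list(ids)
    perm = rng.permutation(len(ids))
    return [ids[i] for i in perm]


@dataclass
class AccumulationCurve:
    x: np.ndarray  # 1..n
    y: np.ndarray  # cumulative unique taxa

    def auc(self) -> float:
        return float(np.trapezoid(self.y, self.x))


def accumulation_curve(order: list[str], labels) -> AccumulationCurve:
    """Cumulative count of unique taxon labels along a pick order."""
    labels = dict(labels) if not isinstance(labels, dict) else labels
    seen: set = set()
    y = np.empty(len(order), dtype=float)
    for i, cid in enumerate(order):
        if cid not in labels or pd.isna(labels[cid]):
            raise ValueError(f"colony {cid!r} in pick order has no taxon label")
        seen.add(labels[cid])
        y[i] = len(seen)
    return AccumulationCurve(x=np.arange(1, len(order) + 1, dtype=float), y=y)


@dataclass
class StrategyComparison:
    auc_a: np.ndarray
    auc_b: np.ndarray
    t: float
    p: float
    degenerate: bool  # True when every paired difference is identical


def compare_strategies(
    curves_a: list[AccumulationCurve], curves_b: list[AccumulationCurve]
) -> StrategyComparison:
    """Two-sided paired t-test on per-replicate area under the curve.

    Curves are truncated to the shortest common length. With all paired
    differences equal the t statistic is undefined; the comparison is flagged
    degenerate with p = 1 when the common difference is zero, p = 0 otherwise.
    """
    if len(curves_a) != len(curves_b):
        raise ValueError("replicate counts differ")
    if len(curves_a) < 2:
        raise ValueError("need at least 2 paired replicates for a t-test")
    n = min(min(len(c.x) for c in curves_a), min(len(c.x) for c in curves_b))
    auc_a = np.array([np.trapezoid(c.y[:n], c.x[:n]) for c in curves_a])
    auc_b = np.array([np.trapezoid(c.y[:n], c.x[:n]) for c in curves_b])
    diffs = auc_a - auc_b
    if np.allclose(diffs.std(ddof=1), 0.0):
        p = 1.0 if np.allclose(diffs.mean(), 0.0) else 0.0
        return StrategyComparison(auc_a, auc_b, float("nan"), p, True)
    t, p = sps.ttest_rel(auc_a, auc_b)
    return StrategyComparison(auc_a, auc_b, float(t), float(p), False)


# ---------------------------------------------------------------------------
# picklists
# ---------------------------------------------------------------------------

_WELL_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well: 16 rows x 24 columns
_WELLS_PER_PLATE = 384


def well_name(index: int) -> str:
    """Row-major well name within a 384-well plate: 0 -> A1, 383 -> P24."""
    if not 0 <= index < _WELLS_PER_PLATE:
        raise ValueError("well index out of range")
    return f"{_WELL_ROWS[index // 24]}{index % 24 + 1}"


def export_picklist(
    colonies: pd.DataFrame, destination_plates: list[str], path=None
) -> pd.DataFrame:
    """Assign picked colonies to destination wells in row-major pick order.

    ``colonies`` must carry colony_id, plate_barcode, x_px, y_px in pick
    order. Raises if the picks exceed 384 x n destination plates.
    """
    capacity = _WELLS_PER_PLATE * len(destination_plates)
    if len(colonies) > capacity:
        raise ValueError(
            f"{len(colonies)} colonies exceed capacity {capacity} "
            f"({len(destination_plates)} plate(s) x {_WELLS_PER_PLATE} wells)"
        )
    if colonies["colony_id"].duplicated().any():
        raise ValueError("duplicate colony in picklist")
    rows = []
    for i, (_, rec) in enumerate(colonies.iterrows()):
        rows.append(
            {
                "plate_barcode": rec["plate_barcode"],
                "colony_id": rec["colony_id"],
                "x_px": rec["x_px"],
                "y_px": rec["y_px"],
                "destination_plate": destination_plates[i // _WELLS_PER_PLATE],
                "destination_well": well_name(i % _WELLS_PER_PLATE),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "plate_barcode",
            "colony_id",
            "x_px",
            "y_px",
            "destination_plate",
            "destination_well",
        ],
    )
    if path is not None:
        out.to_csv(path, index=False)
    return out
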