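"""Alpha and beta diversity of the bifidobacterial community.

Alpha diversity on the rarefied ZOTU table: observed ZOTUs, Shannon index
(natural log) and Faith's phylogenetic diversity (total branch length of
the minimal subtree connecting the observed tips and the root).  Beta
diversity: Bray-Curtis dissimilarity and Jensen-Shannon divergence (the
divergence itself, natural log, so the range is [0, ln 2]).  The
adjacent-age trajectory measures community turnover along the lifespan:
all cross-sample Bray-Curtis distances between each integer age bin and
the bin one year younger.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon, pdist, squareform
from skbio import DistanceMatrix, TreeNode
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts: np.ndarray) -> float:
    """Shannon entropy (natural log) of a count or abundance vector."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        return 0.0
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def faith_pd(tree: TreeNode, observed_tips: Sequence[str]) -> float:
    """Faith's PD: branch length of the minimal subtree spanning the
    observed tips and the root (root path included)."""
    tips = {t.name: t for t in tree.tips()}
    missing = [n for n in observed_tips if n not in tips]
    if missing:
        raise KeyError(f"tips not in tree: {missing[:10]}")
    seen: set[int] = set()
    total = 0.0
    for name in set(observed_tips):
        node = tips[name]
        while node.parent is not None:
            if id(node) in seen:
                break
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def alpha_diversity(table: pd.DataFrame, tree: Optional[TreeNode] = None) -> pd.DataFrame:
    """Per-sample observed ZOTUs, Shannon index, and (with a tree) Faith's PD."""
    counts = table.to_numpy(dtype=float)
    out = pd.DataFrame(index=table.index)
    out["observed"] = (counts > 0).sum(axis=1)
    out["shannon"] = [shannon(row) for row in counts]
    if tree is None:
        logger.warning("no tree provided; Faith's PD omitted")
    else:
        cols = np.asarray(table.columns)
        out["faiths_pd"] = [
            faith_pd(tree, list(cols[row > 0])) if row.sum() > 0 else 0.0
            for row in counts
        ]
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def jsd(x: np.ndarray, y: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) of two abundance vectors,
    renormalized to probability distributions."""
    # scipy returns the JS *distance* = sqrt(divergence)
    return float(jensenshannon(np.asarray(x, float), np.asarray(y, float), base=np.e) ** 2)


def beta_diversity(table: pd.DataFrame, metric: str = "bray_curtis") -> DistanceMatrix:
    """All-pairs distance matrix under Bray-Curtis or Jensen-Shannon."""
    X = table.to_numpy(dtype=float)
    sums = X.sum(axis=1)
    if (sums == 0).any():
        bad = list(table.index[sums == 0])
        raise ValueError(f"zero-sum samples cannot be compared: {bad[:10]}")
    if metric == "bray_curtis":
        condensed = pdist(X, metric="braycurtis")
    elif metric == "jsd":
        P = X / sums[:, None]
        condensed = pdist(P, metric=lambda a, b: jensenshannon(a, b, base=np.e) ** 2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


# ---------------------------------------------------------------------------
# age trajectories
# ---------------------------------------------------------------------------

def adjacent_age_dissimilarity(
    profiles: pd.DataFrame,
    ages: pd.Series,
    span: float = 0.75,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bray-Curtis turnover between communities one year apart.

    Ages are floored to integer bins (infants under 1 occupy bin 0).  For
    every bin ``a`` whose bin ``a-1`` is occupied, all cross pairs between
    the two bins contribute one distance each, recorded at bin ``a``.
    Returns the point cloud and a loess trend over the points.
    """
    ages = ages.loc[profiles.index].astype(float)
    if (ages < 0).any():
        raise ValueError("ages must be non-negative")
    bins = np.floor(ages).astype(int)
    by_bin: dict[int, list] = {}
    for sample, b in bins.items():
        by_bin.setdefault(int(b), []).append(sample)
    rows = []
    for b in sorted(by_bin):
        if b - 1 not in by_bin:
            continue
        for s in by_bin[b]:
            x = profiles.loc[s].to_numpy(dtype=float)
            for t in by_bin[b - 1]:
                rows.append((b, s, t, bray_curtis(x, profiles.loc[t].to_numpy(dtype=float))))
    points = pd.DataFrame(rows, columns=["age_bin", "sample", "neighbor", "distance"])
    if len(points) >= 3 and points["age_bin"].nunique() >= 2:
        sm = lowess(points["distance"], points["age_bin"], frac=span)
        trend = pd.DataFrame(sm, columns=["age_bin", "distance"]).drop_duplicates("age_bin")
    else:
        trend = pd.DataFrame(columns=["age_bin", "distance"])
    return points, trend


def age_trend(
    feature: pd.Series,
    ages: pd.Series,
    span: float = 0.75,
    grid: Optional[np.ndarray] = None,
    annotate_at: tuple[float, ...] = (16.0, 30.0),
) -> dict:
    """Loess curve and linear fit of one feature against age.

    The ages 16 and 30 are descriptive annotation points on the smoothed
    curve (no change-point detection is performed).
    """
    y = feature.astype(float).to_numpy()
    x = ages.loc[feature.index].astype(float).to_numpy()
    if len(y) < 10:
        raise ValueError("need at least 10 samples for an age trend")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    if np.ptp(y) == 0:
        logger.warning("constant feature; loess is degenerate")
        curve = np.full_like(grid, y[0], dtype=float)
        slope, se, p = 0.0, 0.0, 1.0
    else:
        curve = lowess(y, x, frac=span, xvals=grid)
        import scipy.stats as st

        res = st.linregress(x, y)
        slope, se, p = float(res.slope), float(res.stderr), float(res.pvalue)
    annotations = {
        a: float(np.interp(a, grid, curve)) for a in annotate_at
        if grid.min() <= a <= grid.max()
    }
    return {
        "grid": grid,
        "loess": curve,
        "slope": slope,
        "slope_se": se,
        "slope_p": p,
        "annotations": annotations,
    }
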