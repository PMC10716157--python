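"""Covariate-association statistics for community profiles.

The battery mirrors what a population-microbiome analysis needs:

* distance-based redundancy analysis (dbRDA): variance in a dissimilarity
  matrix explained by a covariate, via a principal-coordinates embedding
  followed by redundancy analysis, with Ezekiel-adjusted R-squared and a
  permutation p-value;
* forward stepwise dbRDA with the adjusted-R-squared scope stopping rule:
  selection halts when the candidate model's adjusted R-squared would
  exceed that of the global (all-covariates) model;
* ridge regression association of a feature (abundance or diversity
  index) with correlated covariates, continuous terms z-scored,
  categorical terms dummy-coded against declared reference levels, the
  penalty chosen by generalized cross-validation;
* Mantel tests, age/sex-adjusted linear models, one-way ANOVA with
  Fisher's LSD compact letters, Mann-Whitney differential gene counts,
  genome-vs-geography correlations, and Benjamini-Hochberg FDR control.

Significance conventions default to raw p < 0.05 and BH-adjusted
p < 0.1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_RAW = 0.05
ALPHA_ADJ = 0.1

#: Reference levels for the cohort's categorical covariates.
DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "sex": "female",
    "ethnicity": "Han",
    "staple_food": "rice",
    "residence": "rural",
    "sampling_month": "April",
}

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEG_LAT = math.pi * EARTH_RADIUS_KM / 180.0


@dataclass
class AssociationResult:
    term: str
    estimate: float
    se: Optional[float]
    p: float
    p_adj: Optional[float]
    n: int


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _is_continuous(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype)


def design_matrix(
    covariates: pd.DataFrame,
    reference_levels: Optional[dict[str, str]] = None,
    zscore_continuous: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Numeric model matrix (no intercept column) from a covariate frame.

    Continuous columns pass through (optionally z-scored); categorical
    columns are dummy-coded with the declared reference level dropped
    (first sorted level otherwise).
    """
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    refs.update(reference_levels or {})
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in covariates.columns:
        s = covariates[name]
        if s.isna().any():
            raise ValueError(f"covariate {name!r} has missing values; "
                             "drop incomplete cases first")
        if _is_continuous(s):
            x = s.to_numpy(dtype=float)
            if zscore_continuous:
                sd = x.std(ddof=1)
                if sd == 0:
                    raise ValueError(f"covariate {name!r} is constant")
                x = (x - x.mean()) / sd
            cols.append(x)
            names.append(name)
        else:
            levels = sorted(map(str, s.unique()))
            if len(levels) < 2:
                raise ValueError(f"categorical covariate {name!r} is constant")
            ref = refs.get(name)
            if ref is not None and ref in levels:
                levels.remove(ref)
            else:
                levels = levels[1:]
            vals = s.astype(str).to_numpy()
            for lev in levels:
                cols.append((vals == lev).astype(float))
                names.append(f"{name}[{lev}]")
    if not cols:
        raise ValueError("no covariates")
    return np.column_stack(cols), names


def complete_cases(df: pd.DataFrame, columns: Sequence[str]) -> pd.Index:
    """Index of rows with no missing value in *columns* (logged)."""
    mask = df[list(columns)].notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("complete cases: %d of %d rows dropped for %s",
                    n_drop, len(df), list(columns))
    return df.index[mask]


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

def pcoa_embedding(dist: np.ndarray, tol: float = 1e-9) -> tuple[np.ndarray, float]:
    """Principal-coordinates embedding of a distance matrix.

    Gower-centers -D^2/2, keeps the positive-eigenvalue axes scaled by
    sqrt(eigenvalue) (negative axes are dropped with a warning), and
    returns the coordinates plus the total retained inertia.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    A = -0.5 * D**2
    row = A.mean(axis=0)
    G = A - row[None, :] - row[:, None] + A.mean()
    w, V = np.linalg.eigh(G)
    cutoff = max(w.max(), 0.0) * tol
    if (w < -cutoff).any():
        neg = float(-w[w < 0].sum())
        logger.warning("PCoA: dropping negative-eigenvalue axes "
                       "(total negative inertia %.4g)", neg)
    keep = w > cutoff
    Y = V[:, keep] * np.sqrt(w[keep])
    return Y, float(w[keep].sum())


def _constrained_fraction(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Fraction of the embedding's inertia captured by the hat projection
    onto the column-centered design X, plus the design's rank (model d.f.)."""
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    rank_keep = diag > max(diag.max(), 1e-300) * 1e-10
    Q = Q[:, rank_keep]
    fitted = Q @ (Q.T @ Y)
    total = float((Y**2).sum())
    return float((fitted**2).sum()) / total, int(rank_keep.sum())


def ezekiel_adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def dbrda_univariate(
    dist,
    covariate: pd.Series,
    n_perm: int = 999,
    seed: Optional[int] = None,
    reference_levels: Optional[dict[str, str]] = None,
) -> AssociationResult:
    """Variance in a dissimilarity matrix explained by one covariate.

    Returns the Ezekiel-adjusted R-squared as the estimate and a
    permutation p-value from row permutations of the covariate.
    """
    D = np.asarray(getattr(dist, "data", dist), dtype=float)
    n = D.shape[0]
    if len(covariate) != n:
        raise ValueError("covariate length does not match the distance matrix")
    if covariate.isna().any():
        raise ValueError("drop incomplete cases before dbRDA")
    X, _ = design_matrix(covariate.to_frame(), reference_levels)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError(f"covariate {covariate.name!r} is constant")
    Y, _ = pcoa_embedding(D)
    r2, m = _constrained_fraction(Y, X)
    adj = ezekiel_adjusted_r2(r2, n, m)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r2p, _ = _constrained_fraction(Y, X[perm])
        if r2p >= r2:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AssociationResult(term=str(covariate.name), estimate=adj, se=None,
                             p=p, p_adj=None, n=n)


def dbrda_r2(dist, covariates: pd.DataFrame,
             reference_levels: Optional[dict[str, str]] = None) -> tuple[float, float, int]:
    """(R2, adjusted R2, model d.f.) of a multi-covariate dbRDA."""
    D = np.asarray(getattr(dist, "data", dist), dtype=float)
    X, _ = design_matrix(covariates, reference_levels)
    Y, _ = pcoa_embedding(D)
    r2, m = _constrained_fraction(Y, X)
    return r2, ezekiel_adjusted_r2(r2, D.shape[0], m), m


def dbrda_stepwise(
    dist,
    candidates: pd.DataFrame,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    reference_levels: Optional[dict[str, str]] = None,
    max_steps: Optional[int] = None,
) -> pd.DataFrame:
    """Forward selection of covariates with the adjusted-R2 scope rule.

    At each step the candidate yielding the largest adjusted R-squared
    (among those improving it, with permutation p <= alpha) is added;
    selection stops when no candidate qualifies or when the model's
    adjusted R-squared would exceed the global model's.  Returns one row
    per selected term: cumulative adjusted R2, its increment, and p.
    ``max_steps`` truncates the path (useful when only the leading terms
    are of interest).
    """
    if candidates.shape[1] < 2:
        raise ValueError("need at least two candidate covariates")
    if candidates.isna().any().any():
        raise ValueError("drop incomplete cases before stepwise dbRDA")
    D = np.asarray(getattr(dist, "data", dist), dtype=float)
    n = D.shape[0]
    Y, _ = pcoa_embedding(D)

    designs = {
        c: design_matrix(candidates[[c]], reference_levels)[0]
        for c in candidates.columns
    }
    X_all = np.column_stack([designs[c] for c in candidates.columns])
    r2_all, m_all = _constrained_fraction(Y, X_all)
    adj_global = ezekiel_adjusted_r2(r2_all, n, m_all)

    rng = np.random.default_rng(seed)
    selected: list[str] = []
    rows = []
    X_cur = np.empty((n, 0))
    adj_cur = 0.0
    remaining = list(candidates.columns)
    while remaining and (max_steps is None or len(selected) < max_steps):
        best = None
        for c in remaining:
            Xc = np.column_stack([X_cur, designs[c]])
            r2_new, m_new = _constrained_fraction(Y, Xc)
            adj_new = ezekiel_adjusted_r2(r2_new, n, m_new)
            if not (adj_new > adj_cur + 1e-12):
                continue
            if best is None or adj_new > best[1]:
                best = (c, adj_new, r2_new)
        if best is None:
            break
        c, adj_new, r2_new = best
        # permutation test of the added term, current terms held fixed
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Xp = np.column_stack([X_cur, designs[c][perm]])
            r2p, _ = _constrained_fraction(Y, Xp)
            if r2p >= r2_new:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        if p > alpha:
            break
        if adj_new > adj_global + 1e-12:  # R2scope rule
            logger.info("stepwise dbRDA: %r would exceed the global adjusted R2; stopping", c)
            break
        rows.append({"term": c, "adj_r2": adj_new, "delta_adj_r2": adj_new - adj_cur,
                     "p": p, "n": n})
        selected.append(c)
        remaining.remove(c)
        X_cur = np.column_stack([X_cur, designs[c]])
        adj_cur = adj_new
    return pd.DataFrame(rows, columns=["term", "adj_r2", "delta_adj_r2", "p", "n"])


# ---------------------------------------------------------------------------
# ridge regression
# ---------------------------------------------------------------------------

def _ridge_svd(X: np.ndarray, y: np.ndarray, lam: float):
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    d = s / (s**2 + lam) if lam > 0 else np.divide(
        1.0, s, out=np.zeros_like(s), where=s > s.max() * 1e-12
    )
    beta = Vt.T @ (d * (U.T @ y))
    edf = float((s**2 / (s**2 + lam)).sum()) if lam > 0 else float((s > s.max() * 1e-12).sum())
    return beta, edf, (U, s, Vt)


def semiauto_lambda(X: np.ndarray, y: np.ndarray, prop_var: float = 0.90) -> float:
    """Semi-automatic ridge penalty from principal-components regression.

    Take the first k principal components of X explaining *prop_var* of
    its variance, fit y on them, and set
    ``lambda = k * sigma^2 / sum_j alpha_j^2`` where alpha are the
    component coefficients and sigma^2 the residual variance of the
    k-component fit.  This generalizes the Hoerl-Kennard-Baldwin
    estimator and keeps the penalty small enough that coefficient bias
    stays negligible, so the t-tests on the ridge coefficients retain
    their nominal level.
    """
    n = len(y)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    pos = s > s.max() * 1e-12
    s = s[pos]
    U = U[:, pos]
    frac = np.cumsum(s**2) / (s**2).sum()
    k = int(np.searchsorted(frac, prop_var) + 1)
    k = min(k, len(s))
    alpha = (U[:, :k].T @ y) / s[:k]
    fitted = U[:, :k] @ (s[:k] * alpha)
    dof = max(n - k - 1, 1)
    sigma2 = float(((y - fitted) ** 2).sum()) / dof
    denom = float((alpha**2).sum())
    if denom <= 0:
        return 0.0
    return k * sigma2 / denom


def gcv_lambda(X: np.ndarray, y: np.ndarray,
               grid: Optional[np.ndarray] = None) -> float:
    """Ridge penalty minimizing generalized cross-validation error."""
    if grid is None:
        grid = np.concatenate([[0.0], np.logspace(-4, 4, 81)])
    n = len(y)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    Uty = U.T @ y
    yy = float(y @ y)
    best_lam, best_gcv = grid[0], np.inf
    for lam in grid:
        shrink = s**2 / (s**2 + lam) if lam > 0 else (s > s.max() * 1e-12).astype(float)
        rss = yy - 2 * float((shrink * Uty) @ Uty) + float((shrink * Uty) @ (shrink * Uty))
        edf = float(shrink.sum())
        if n - edf <= 0:
            continue
        gcv = n * rss / (n - edf) ** 2
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, float(lam)
    return best_lam


def ridge_associate(
    y: pd.Series,
    covariates: pd.DataFrame,
    lam: float | str = "auto",
    reference_levels: Optional[dict[str, str]] = None,
) -> list[AssociationResult]:
    """Ridge association of one feature with a covariate frame.

    The response and continuous covariates are z-scored; categorical
    covariates are dummy-coded against the reference levels.  With
    ``lam="auto"`` the penalty comes from the principal-components
    semi-automatic estimator (``lam="gcv"`` selects by generalized
    cross-validation instead, which shrinks harder and trades coefficient
    bias for prediction error).  Standard errors come from the ridge
    sandwich ``sigma^2 (X'X+lI)^-1 X'X (X'X+lI)^-1`` and p-values from a
    t reference with n - edf degrees of freedom.
    """
    idx = complete_cases(pd.concat([y.rename("__y"), covariates], axis=1),
                         ["__y", *covariates.columns])
    yv = y.loc[idx].to_numpy(dtype=float)
    n = len(yv)
    X, names = design_matrix(covariates.loc[idx], reference_levels,
                             zscore_continuous=True)
    if n < X.shape[1]:
        raise ValueError("fewer complete cases than model columns")
    sd = yv.std(ddof=1)
    yz = (yv - yv.mean()) / sd if sd > 0 else yv - yv.mean()
    Xc = X - X.mean(axis=0)

    if lam == "auto":
        lam_val = semiauto_lambda(Xc, yz)
    elif lam == "gcv":
        lam_val = gcv_lambda(Xc, yz)
    else:
        lam_val = float(lam)
        if lam_val < 0:
            raise ValueError("ridge penalty must be non-negative")
    beta, edf, (U, s, Vt) = _ridge_svd(Xc, yz, lam_val)
    resid = yz - Xc @ beta
    dof = max(n - edf, 1.0)
    sigma2 = float(resid @ resid) / dof
    # Var(beta) = sigma^2 V diag(s^2/(s^2+lam)^2) V'
    if lam_val > 0:
        var_diag = (Vt.T**2) @ (s**2 / (s**2 + lam_val) ** 2)
    else:
        inv = np.divide(1.0, s**2, out=np.zeros_like(s), where=s > s.max() * 1e-12)
        var_diag = (Vt.T**2) @ inv
    se = np.sqrt(sigma2 * var_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * st.t.sf(np.abs(tstat), dof)
    return [
        AssociationResult(term=name, estimate=float(b), se=float(e), p=float(p),
                          p_adj=None, n=n)
        for name, b, e, p in zip(names, beta, se, pvals)
    ]


def ridge_associate_table(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    lam: float | str = "auto",
    reference_levels: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Ridge associations for every feature column, BH-adjusted across
    features within each model term (tidy output)."""
    rows = []
    for feat in features.columns:
        for res in ridge_associate(features[feat], covariates, lam, reference_levels):
            rows.append({"feature": feat, "term": res.term, "estimate": res.estimate,
                         "se": res.se, "p": res.p, "n": res.n})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for term, sub in out.groupby("term"):
        out.loc[sub.index, "p_adj"] = bh_adjust(sub["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(d1, d2, n_perm: int = 999, seed: Optional[int] = None) -> tuple[float, float]:
    """Mantel correlation of two distance matrices with a one-sided
    (greater) permutation p-value under row/column permutations of d2."""
    A = np.asarray(getattr(d1, "data", d1), dtype=float)
    B = np.asarray(getattr(d2, "data", d2), dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrices must be square and conformable")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    r_obs = float(st.pearsonr(a, B[iu])[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if st.pearsonr(a, B[np.ix_(perm, perm)][iu])[0] >= r_obs:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# adjusted linear models
# ---------------------------------------------------------------------------

def linreg_adjusted(
    y: pd.Series,
    target: pd.Series,
    adjust: pd.DataFrame,
    reference_levels: Optional[dict[str, str]] = None,
) -> AssociationResult:
    """OLS association of a feature with a target covariate, adjusting
    for the given confounders (age and sex in the standard battery)."""
    frame = pd.concat([y.rename("__y"), target.rename("__t"), adjust], axis=1)
    idx = complete_cases(frame, frame.columns)
    if len(idx) < 10:
        raise ValueError("need at least 10 complete cases")
    design = pd.concat([target.rename(str(target.name) or "target"), adjust], axis=1).loc[idx]
    X, names = design_matrix(design, reference_levels, zscore_continuous=True)
    yv = y.loc[idx].to_numpy(dtype=float)
    sd = yv.std(ddof=1)
    yz = (yv - yv.mean()) / sd if sd > 0 else yv - yv.mean()
    Xd = np.column_stack([np.ones(len(idx)), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        raise ValueError(f"rank-deficient design; check columns {names}")
    beta, _, _, _ = np.linalg.lstsq(Xd, yz, rcond=None)
    resid = yz - Xd @ beta
    dof = len(idx) - Xd.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = float(np.sqrt(cov[1, 1]))
    tstat = beta[1] / se if se > 0 else 0.0
    p = float(2 * st.t.sf(abs(tstat), dof))
    return AssociationResult(term=names[0], estimate=float(beta[1]), se=se,
                             p=p, p_adj=None, n=len(idx))


# ---------------------------------------------------------------------------
# ANOVA + Fisher's LSD compact letters
# ---------------------------------------------------------------------------

def _maximal_cliques(adjacency: dict[int, set[int]]) -> list[set[int]]:
    """Bron-Kerbosch maximal cliques of a small undirected graph."""
    cliques: list[set[int]] = []

    def expand(r: set[int], p: set[int], x: set[int]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in sorted(p):
            expand(r | {v}, p & adjacency[v], x & adjacency[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(adjacency), set())
    return cliques


def anova_lsd_letters(
    y: pd.Series,
    group: pd.Series,
    alpha_adj: float = ALPHA_ADJ,
) -> dict:
    """One-way ANOVA plus Fisher's-LSD pairwise tests with BH-adjusted
    p-values and a compact letter display.

    Groups sharing a letter are not significantly different at
    p.adj < *alpha_adj*.  Groups with fewer than two samples are dropped.
    """
    frame = pd.DataFrame({"y": y.astype(float), "g": group.astype(str)}).dropna()
    sizes = frame.groupby("g").size()
    small = sizes[sizes < 2].index
    if len(small):
        logger.warning("dropping groups with < 2 samples: %s", list(small))
        frame = frame[~frame["g"].isin(small)]
    levels = sorted(frame["g"].unique())
    if len(levels) < 1:
        raise ValueError("no groups with at least two samples")
    groups = {g: frame.loc[frame["g"] == g, "y"].to_numpy() for g in levels}
    k = len(levels)
    N = len(frame)
    if k == 1:
        return {"f": float("nan"), "p": float("nan"),
                "letters": {levels[0]: "a"}, "pairs": pd.DataFrame()}

    grand = frame["y"].mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, N - k
    mse = ss_within / df_w
    f = (ss_between / df_b) / mse if mse > 0 else float("inf")
    p_anova = float(st.f.sf(f, df_b, df_w))

    pairs = []
    for g1, g2 in itertools.combinations(levels, 2):
        a, b = groups[g1], groups[g2]
        if mse == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
            tstat = float("inf") if p == 0 else 0.0
        else:
            se = math.sqrt(mse * (1 / len(a) + 1 / len(b)))
            tstat = (a.mean() - b.mean()) / se
            p = float(2 * st.t.sf(abs(tstat), df_w))
        pairs.append({"group1": g1, "group2": g2, "t": tstat, "p": p})
    pair_df = pd.DataFrame(pairs)
    pair_df["p_adj"] = bh_adjust(pair_df["p"].to_numpy())

    # compact letter display: letters = maximal cliques of the
    # "not significantly different" graph
    nonsig = {i: {i} for i in range(k)}
    for _, row in pair_df.iterrows():
        if row["p_adj"] >= alpha_adj:
            i, j = levels.index(row["group1"]), levels.index(row["group2"])
            nonsig[i].add(j)
            nonsig[j].add(i)
    adjacency = {i: nonsig[i] - {i} for i in range(k)}
    cliques = _maximal_cliques(adjacency)
    cliques.sort(key=lambda c: (min(c), -len(c)))
    letters: dict[str, str] = {g: "" for g in levels}
    for letter_idx, clique in enumerate(cliques):
        ch = chr(ord("a") + letter_idx)
        for i in sorted(clique):
            letters[levels[i]] += ch
    return {"f": float(f), "p": p_anova, "letters": letters, "pairs": pair_df}


# ---------------------------------------------------------------------------
# Mann-Whitney differential counts
# ---------------------------------------------------------------------------

def mann_whitney(a: np.ndarray, b: np.ndarray, exact_max_n: int = 16) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    For small pooled samples the p-value is exact, computed by
    enumerating all group assignments of the pooled observations; the
    two-sided p is the fraction of assignments whose U deviates from its
    null mean at least as much as observed.  Constant pooled data gives
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(len(a) * len(b) / 2.0), 1.0
    n1, n2 = len(a), len(b)
    ranks = st.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= exact_max_n:
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu) - 1e-12
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
            if abs(u - mu) >= dev:
                hits += 1
            total += 1
        return u_obs, hits / total
    res = st.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def mw_differential_counts(counts_a: pd.DataFrame, counts_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene-family two-sided Mann-Whitney tests between two genome
    groups, BH-adjusted across families, with the median-difference sign."""
    families = [c for c in counts_a.columns if c in set(counts_b.columns)]
    if not families:
        raise ValueError("no shared gene families")
    rows = []
    for fam in families:
        a = counts_a[fam].to_numpy(dtype=float)
        b = counts_b[fam].to_numpy(dtype=float)
        u, p = mann_whitney(a, b)
        rows.append({"family": fam, "U": u, "p": p,
                     "direction": int(np.sign(np.median(a) - np.median(b))),
                     "n_a": len(a), "n_b": len(b)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# genome distance vs geography
# ---------------------------------------------------------------------------

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def genome_geo_correlation(genome_dist, sites: pd.DataFrame) -> dict:
    """Pearson correlation of genome distances with geographic distance,
    and its latitudinal / longitudinal decomposition, over genome pairs.

    *sites* maps genome id -> (lat, lon); pairs with missing coordinates
    are excluded with a reported count.  Degenerate predictors (all
    genomes co-located) yield NaN correlations.
    """
    D = np.asarray(getattr(genome_dist, "data", genome_dist), dtype=float)
    ids = list(getattr(genome_dist, "ids", sites.index))
    coords = sites.reindex(ids)
    gd, latd, lond, md = [], [], [], []
    n_excluded = 0
    for i, j in itertools.combinations(range(len(ids)), 2):
        lat1, lon1 = coords.iloc[i][["lat", "lon"]]
        lat2, lon2 = coords.iloc[j][["lat", "lon"]]
        if pd.isna(lat1) or pd.isna(lon1) or pd.isna(lat2) or pd.isna(lon2):
            n_excluded += 1
            continue
        gd.append(haversine_km(lat1, lon1, lat2, lon2))
        latd.append(abs(lat1 - lat2) * KM_PER_DEG_LAT)
        mean_lat = math.radians((lat1 + lat2) / 2)
        lond.append(abs(lon1 - lon2) * KM_PER_DEG_LAT * math.cos(mean_lat))
        md.append(D[i, j])
    out = {"n_pairs": len(md), "n_excluded": n_excluded}
    md_arr = np.asarray(md)
    for key, pred in (("geo", gd), ("lat", latd), ("lon", lond)):
        pred_arr = np.asarray(pred)
        if len(pred_arr) < 3 or pred_arr.std() == 0 or md_arr.std() == 0:
            out[f"r_{key}"], out[f"p_{key}"] = float("nan"), float("nan")
        else:
            r, p = st.pearsonr(pred_arr, md_arr)
            out[f"r_{key}"], out[f"p_{key}"] = float(r), float(p)
    return out
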