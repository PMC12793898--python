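"""Distance-based multivariate statistics.

All routines here operate on a sample dissimilarity matrix and share
one algebraic backbone: the Gower-centered inner-product matrix

    G = -(1/2) * J A J,   A_ij = d_ij^2,   J = I - (1/n) 11'

whose trace is the total sum of squared deviations and whose
eigendecomposition gives principal coordinates (PCoA).  Partitioning
tr(G) over a sequence of design matrices yields PERMANOVA sums of
squares; projecting the principal coordinates onto external predictors
yields distance-based redundancy analysis (dbRDA); distances to group
centroids in the PCoA embedding give the dispersion test (PERMDISP).

Permutation p-values use the add-one convention
p = (1 + #{permuted statistic >= observed}) / (1 + n_perm) under free
exchange of sample labels, with an explicit integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import AnalysisError, ConfigError
from .types import DistanceMatrix, OrdinationResult

log = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# distances

def pairwise_distances(
    x: np.ndarray, metric: str = "EUCLIDEAN", samples: list[str] | None = None
) -> DistanceMatrix:
    """Sample-by-sample dissimilarities of a numeric data matrix.

    ``EUCLIDEAN`` accepts any real matrix; ``JACCARD`` and
    ``SIMPLE_MATCHING`` require strictly 0/1 input.
    """
    x = np.asarray(x, dtype=float)
    if np.isnan(x).all(axis=1).any():
        raise AnalysisError("data matrix has an all-missing row")
    if samples is None:
        samples = [f"S{i}" for i in range(x.shape[0])]
    metric = metric.upper()
    if metric == "EUCLIDEAN":
        d = squareform(pdist(x, metric="euclidean"))
    elif metric in ("JACCARD", "SIMPLE_MATCHING"):
        if not np.isin(x[~np.isnan(x)], (0.0, 1.0)).all():
            raise AnalysisError(f"{metric} requires binary 0/1 input")
        scipy_name = "jaccard" if metric == "JACCARD" else "hamming"
        d = squareform(pdist(x, metric=scipy_name))
    else:
        raise ConfigError(f"unknown metric {metric!r}")
    return DistanceMatrix(samples=list(samples), d=d)


# ---------------------------------------------------------------------------
# shared algebra

def gower_center(d: np.ndarray) -> np.ndarray:
    """-(1/2) J D^2 J; its trace equals the total sum of squares."""
    a = -0.5 * np.asarray(d, dtype=float) ** 2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _design_matrix(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment contrasts (drop-first) for a factor."""
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise AnalysisError(f"factor has a single level {levels!r}; nothing to test")
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])


def _hat(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of x (pinv-based)."""
    return x @ np.linalg.pinv(x)


def _term_projectors(terms: dict[str, np.ndarray], n: int) -> tuple[list[str], list[np.ndarray], list[int]]:
    """Cumulative hat matrices for intercept + sequential terms.

    Returns term names, the *incremental* projector list (H_k includes
    terms 1..k plus intercept), and the rank added by each term.
    """
    names = list(terms)
    ones = np.ones((n, 1))
    design = ones
    hats = [_hat(ones)]
    dfs = []
    for name in names:
        t = np.asarray(terms[name])
        if t.ndim == 2:  # pre-built numeric design block
            cols = t.astype(float) - t.astype(float).mean(axis=0)
        elif t.dtype.kind in "fiu":  # numeric covariate
            cols = t.astype(float).reshape(-1, 1) - t.astype(float).mean()
        else:  # factor labels
            cols = _design_matrix(t)
        design = np.column_stack([design, cols])
        h = _hat(design)
        rank_added = int(round(np.trace(h) - np.trace(hats[-1])))
        dfs.append(rank_added)
        hats.append(h)
    return names, hats, dfs


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaTerm:
    name: str
    ss: float
    df: int
    F: float
    R2: float
    p: float


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    ss_residual: float
    df_residual: int
    ss_total: float
    n_perm: int
    seed: int

    @property
    def r2_residual(self) -> float:
        return self.ss_residual / self.ss_total

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "SS": t.ss, "df": t.df, "F": t.F, "R2": t.R2, "p": t.p}
            for t in self.terms
        ]
        rows.append({
            "term": "Residual", "SS": self.ss_residual, "df": self.df_residual,
            "F": float("nan"), "R2": self.r2_residual, "p": float("nan"),
        })
        return pd.DataFrame(rows)


def _sequential_ss(g: np.ndarray, hats: list[np.ndarray]) -> np.ndarray:
    """SS explained by each successive term: tr(H_k G) - tr(H_{k-1} G)."""
    tr = np.array([(h * g).sum() for h in hats])  # tr(H G), H symmetric
    return np.diff(tr)


def permanova(
    d: DistanceMatrix,
    terms: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (Type-I) terms.

    ``terms`` maps term name to a per-sample factor (labels) or numeric
    covariate, tested in the given order.  Pseudo-F for each term is
    (SS_term/df_term)/(SS_res/df_res); significance comes from freely
    permuting sample identities (rows/columns of the distance matrix).

    With ``exhaustive=True`` every one of the n! relabelings is
    evaluated (feasible for n <= 9) and p is the exact fraction of
    relabelings — the identity included — whose F is at least the
    observed F; otherwise ``n_perm`` random permutations are drawn and
    p uses the add-one convention.
    """
    if not exhaustive and n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    n = d.n
    for name, t in terms.items():
        if len(np.asarray(t)) != n:
            raise AnalysisError(f"term {name!r} length != number of samples")
    g = gower_center(d.d)
    ss_total = float(np.trace(g))
    names, hats, dfs = _term_projectors(terms, n)
    ss_terms = _sequential_ss(g, hats)
    ss_model = float((hats[-1] * g).sum() - (hats[0] * g).sum())
    ss_res = ss_total - ss_model
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise AnalysisError("no residual degrees of freedom")
    ms_res = ss_res / df_res
    f_obs = np.array([ss_terms[k] / dfs[k] / ms_res for k in range(len(names))])

    exceed = np.zeros(len(names))
    h_stack = np.stack(hats)  # (K+1, n, n)
    block = max(1, int(2e6 // (n * n)))
    if exhaustive:
        from itertools import permutations as _iperm
        from math import factorial
        if factorial(n) > 500_000:
            raise ConfigError("exhaustive enumeration is limited to n <= 9")
        perms = np.array(list(_iperm(range(n))), dtype=np.intp)
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    for start in range(0, n_perm, block):
        pb = perms[start:start + block]
        gp = g[pb[:, :, None], pb[:, None, :]]  # (B, n, n)
        tr = np.einsum("kij,bij->bk", h_stack, gp)
        ssb = np.diff(tr, axis=1)  # (B, K)
        ss_res_b = ss_total - (tr[:, -1] - tr[:, 0])
        fb = (ssb / np.array(dfs)) / (ss_res_b / df_res)[:, None]
        exceed += (fb >= f_obs - _EPS).sum(axis=0)

    if exhaustive:
        p = exceed / n_perm
    else:
        p = (1.0 + exceed) / (1.0 + n_perm)
    result = PermanovaResult(
        terms=[
            PermanovaTerm(
                name=names[k], ss=float(ss_terms[k]), df=dfs[k],
                F=float(f_obs[k]), R2=float(ss_terms[k] / ss_total), p=float(p[k]),
            )
            for k in range(len(names))
        ],
        ss_residual=float(ss_res), df_residual=df_res,
        ss_total=ss_total, n_perm=n_perm, seed=seed,
    )
    return result


# ---------------------------------------------------------------------------
# PCoA

def pcoa(d: DistanceMatrix, correction: str = "DROP_NEGATIVE") -> OrdinationResult:
    """Principal coordinates analysis (classical metric MDS).

    ``correction`` handles negative eigenvalues from non-Euclidean
    dissimilarities: ``DROP_NEGATIVE`` (default) discards them,
    ``NONE`` keeps them in the eigenvalue report (coordinates still use
    positive axes only), ``LINGOES`` adds the additive constant that
    makes the configuration Euclidean before re-decomposing.
    Explained fractions are relative to the sum of retained positive
    eigenvalues.
    """
    correction = correction.upper()
    if correction not in ("NONE", "DROP_NEGATIVE", "LINGOES"):
        raise ConfigError(f"unknown PCoA correction {correction!r}")
    dm = d.d
    if np.allclose(dm, 0.0):
        log.warning("all-zero distance matrix; returning zero coordinates")
        return OrdinationResult(
            kind="PCOA", samples=list(d.samples),
            coordinates=np.zeros((d.n, 1)), eigenvalues=np.zeros(1),
            explained=np.zeros(1),
        )
    g = gower_center(dm)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if correction == "LINGOES" and eigval[-1] < -1e-9:
        c = -eigval[-1]
        d2 = dm ** 2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        g = gower_center(np.sqrt(d2))
        eigval, eigvec = np.linalg.eigh(g)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]

    pos = eigval > max(eigval[0], 0.0) * 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_sum = eigval[pos].sum()
    if correction == "NONE":
        kept_eig = eigval
    else:
        kept_eig = eigval[pos]
    explained = np.where(kept_eig > 0, kept_eig / pos_sum, 0.0)
    return OrdinationResult(
        kind="PCOA", samples=list(d.samples),
        coordinates=coords, eigenvalues=kept_eig, explained=explained,
    )


def group_centroids(ordination: OrdinationResult, groups: np.ndarray) -> dict[str, np.ndarray]:
    """Arithmetic-mean centroid of each group in ordination space."""
    groups = np.asarray(groups)
    if len(groups) != len(ordination.samples):
        raise AnalysisError("groups length != number of ordinated samples")
    out = {}
    for g in pd.unique(groups):
        members = groups == g
        if not members.any():
            log.warning("empty group %r omitted from centroids", g)
            continue
        out[str(g)] = ordination.coordinates[members].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# PERMDISP

def permdisp(
    d: DistanceMatrix,
    groups: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Homogeneity of multivariate dispersions (distance to group centroid).

    Samples are embedded by PCoA keeping real and imaginary parts
    (negative-eigenvalue axes enter the centroid distance with a minus
    sign, per the standard construction).  The observed statistic is the
    one-way F of those distances across groups; significance comes from
    permuting the distances among groups.  Groups of size 1 are excluded
    with a warning.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise AnalysisError("groups length != number of samples")
    levels, counts = np.unique(groups, return_counts=True)
    small = levels[counts < 2]
    if len(small):
        log.warning("excluding singleton group(s) from PERMDISP: %s", list(small))
        keep = ~np.isin(groups, small)
        d = DistanceMatrix(
            samples=[s for s, k in zip(d.samples, keep) if k],
            d=d.d[np.ix_(keep, keep)],
        )
        groups = groups[keep]
        levels = levels[counts >= 2]
    if len(levels) < 2:
        raise AnalysisError("PERMDISP needs >= 2 groups with >= 2 samples")

    g = gower_center(d.d)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    real = eigvec[:, eigval > tol] * np.sqrt(eigval[eigval > tol])
    imag = eigvec[:, eigval < -tol] * np.sqrt(-eigval[eigval < -tol])

    z = np.empty(len(groups))
    for lv in levels:
        m = groups == lv
        dr2 = ((real[m] - real[m].mean(axis=0)) ** 2).sum(axis=1)
        di2 = ((imag[m] - imag[m].mean(axis=0)) ** 2).sum(axis=1) if imag.size else 0.0
        z[m] = np.sqrt(np.clip(dr2 - di2, 0.0, None))

    def anova_f(vals: np.ndarray) -> float:
        grand = vals.mean()
        ssb = sum((vals[groups == lv].mean() - grand) ** 2 * (groups == lv).sum() for lv in levels)
        ssw = sum(((vals[groups == lv] - vals[groups == lv].mean()) ** 2).sum() for lv in levels)
        dfb, dfw = len(levels) - 1, len(vals) - len(levels)
        if ssw < _EPS:
            return 0.0 if ssb < _EPS else np.inf
        return (ssb / dfb) / (ssw / dfw)

    f_obs = anova_f(z)
    rng = np.random.default_rng(seed)
    exceed = sum(anova_f(rng.permutation(z)) >= f_obs - _EPS for _ in range(n_perm))
    p = (1.0 + exceed) / (1.0 + n_perm)
    return float(f_obs), float(p)


# ---------------------------------------------------------------------------
# RDA variance partitioning

def rda_partition(y: np.ndarray, terms: dict[str, np.ndarray]) -> dict[str, float]:
    """Sequential fractions of total response variance explained per term.

    ``y`` is a samples x responses matrix (centered internally); each
    term is a factor or numeric covariate.  Returns term -> fraction
    plus ``"combined"``.  A term adding no rank contributes 0 with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y.reshape(-1, 1)
    yc = y - y.mean(axis=0)
    total = (yc ** 2).sum()
    if total < _EPS:
        raise AnalysisError("response matrix has zero variance")
    g = yc @ yc.T
    names, hats, dfs = _term_projectors(terms, y.shape[0])
    ss = _sequential_ss(g, hats)
    out = {}
    for k, name in enumerate(names):
        if dfs[k] == 0:
            log.warning("term %r adds no rank; fraction 0", name)
        out[name] = float(max(ss[k], 0.0) / total)
    out["combined"] = float(sum(out[n] for n in names))
    return out


# ---------------------------------------------------------------------------
# dbRDA

@dataclass
class DbrdaResult:
    ordination: OrdinationResult
    constrained_fraction: float
    p_overall: float
    p_per_predictor: dict[str, float]
    n_perm: int
    seed: int


def dbrda(
    d: DistanceMatrix,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    permute: str = "labels",
) -> DbrdaResult:
    """Distance-based redundancy analysis.

    PCoA embeds the dissimilarities on their positive-eigenvalue axes;
    the embedding is then regressed on the (centered) predictor columns.
    The constrained fraction is constrained inertia / total inertia.
    Overall and marginal per-predictor significance come from
    permutation — ``permute="labels"`` shuffles whole samples,
    ``"residuals"`` shuffles reduced-model residuals.
    """
    if permute not in ("labels", "residuals"):
        raise ConfigError(f"unknown permutation scheme {permute!r}")
    for col in predictors.columns:
        if np.std(predictors[col].to_numpy(dtype=float)) < _EPS:
            raise AnalysisError(f"zero-variance predictor {col!r}")
    if predictors.isna().any().any():
        raise AnalysisError("predictors must be complete for all samples")

    emb = pcoa(d, correction="DROP_NEGATIVE")
    y = emb.coordinates - emb.coordinates.mean(axis=0)
    total = (y ** 2).sum()
    x = predictors.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    n, q = x.shape
    h = _hat(x)
    df_model = int(round(np.trace(h)))
    df_res = n - df_model - 1

    ss_c = float(((h @ y) ** 2).sum())
    ss_r = total - ss_c
    if df_res <= 0:
        raise AnalysisError("more predictors than residual degrees of freedom")
    f_obs = (ss_c / df_model) / (ss_r / df_res)

    rng = np.random.default_rng(seed)

    def perm_y(yy: np.ndarray, h_reduced: np.ndarray | None) -> np.ndarray:
        idx = rng.permutation(n)
        if permute == "labels" or h_reduced is None:
            return yy[idx]
        fitted = h_reduced @ yy
        resid = yy - fitted
        return fitted + resid[idx]

    exceed = 0
    for _ in range(n_perm):
        yp = perm_y(y, None)
        ss_cp = float(((h @ yp) ** 2).sum())
        fp = (ss_cp / df_model) / ((total - ss_cp) / df_res)
        if fp >= f_obs - _EPS:
            exceed += 1
    p_overall = (1.0 + exceed) / (1.0 + n_perm)

    # marginal tests: full model vs model without each predictor
    p_marginal = {}
    for j, col in enumerate(predictors.columns):
        x_red = np.delete(x, j, axis=1)
        h_red = _hat(x_red) if x_red.shape[1] else np.zeros((n, n))
        ss_j = ss_c - float(((h_red @ y) ** 2).sum())
        df_j = df_model - int(round(np.trace(h_red)))
        if df_j <= 0:
            p_marginal[col] = float("nan")
            continue
        f_j = (ss_j / df_j) / (ss_r / df_res)
        exceed_j = 0
        for _ in range(n_perm):
            yp = perm_y(y, h_red if permute == "residuals" else None)
            ss_cp = float(((h @ yp) ** 2).sum())
            ss_jp = ss_cp - float(((h_red @ yp) ** 2).sum())
            fjp = (ss_jp / df_j) / ((total - ss_cp) / df_res)
            if fjp >= f_j - _EPS:
                exceed_j += 1
        p_marginal[col] = (1.0 + exceed_j) / (1.0 + n_perm)

    # constrained axes: SVD of the fitted values
    fitted = h @ y
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    keep = s > (s[0] if s.size else 0.0) * 1e-9
    axes = u[:, keep] * s[keep]
    eig = s[keep] ** 2
    ordination = OrdinationResult(
        kind="DBRDA", samples=list(d.samples), coordinates=axes,
        eigenvalues=eig, explained=eig / total if total > 0 else eig,
    )
    return DbrdaResult(
        ordination=ordination,
        constrained_fraction=float(ss_c / total),
        p_overall=float(p_overall),
        p_per_predictor=p_marginal,
        n_perm=n_perm,
        seed=seed,
    )
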