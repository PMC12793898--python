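"""Discriminant analysis of principal components (DAPC).

DAPC first reduces the (centered) feature matrix to a small number of
principal components — by convention k - 1 for k groups — and then finds
linear discriminant axes in that reduced space maximising the
between-group to within-group variance ratio.  Discriminant directions
are back-projected through the PCA rotation so each original feature
(locus) receives a loading per axis; loadings are reported as squared
contributions normalised to sum to 1 per axis, which makes the
percentile-based "influential locus" rule scale-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .errors import AnalysisError

log = logging.getLogger(__name__)


@dataclass
class DapcResult:
    n_pc_retained: int
    n_da: int
    samples: list[str]
    sample_scores: np.ndarray  # samples x discriminant axes
    loadings: pd.DataFrame  # features x axes, squared normalized contributions
    group_assignment: np.ndarray
    separation: float  # between/within variance ratio on axis 1


def fit_dapc(
    x: np.ndarray,
    groups: np.ndarray,
    n_pc: int | None = None,
    n_da: int = 2,
    feature_names: list[str] | None = None,
    samples: list[str] | None = None,
    ridge: float = 1e-8,
) -> DapcResult:
    """Fit DAPC on a samples x features matrix.

    ``n_pc`` defaults to (number of groups - 1); ``n_da`` defaults to 2
    and is capped at min(n_pc, k - 1).  A singular within-group scatter
    is ridge-stabilised with a warning.
    """
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    n, p = x.shape
    levels = pd.unique(groups)
    k = len(levels)
    if k < 2:
        raise AnalysisError("DAPC needs >= 2 groups")
    if n_pc is None:
        n_pc = k - 1
    if n_pc < 1:
        raise AnalysisError("n_pc must be >= 1")
    if n_pc >= n:
        raise AnalysisError(f"n_pc={n_pc} must be < sample count {n}")
    n_da = min(n_da, n_pc, k - 1)

    xc = x - x.mean(axis=0)
    # PCA via thin SVD; retain n_pc axes
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    n_pc_eff = min(n_pc, rank)
    if n_pc_eff < n_pc:
        log.warning("matrix rank %d < requested n_pc %d; retaining %d", rank, n_pc, n_pc_eff)
    rot = vt[:n_pc_eff].T  # p x n_pc
    scores = xc @ rot  # n x n_pc

    # between/within scatter in PC space
    sw = np.zeros((n_pc_eff, n_pc_eff))
    sb = np.zeros((n_pc_eff, n_pc_eff))
    grand = scores.mean(axis=0)
    for lv in levels:
        m = groups == lv
        mu = scores[m].mean(axis=0)
        dev = scores[m] - mu
        sw += dev.T @ dev
        sb += m.sum() * np.outer(mu - grand, mu - grand)
    if np.linalg.matrix_rank(sw) < n_pc_eff:
        log.warning("singular within-group scatter; ridge-stabilising")
    sw_reg = sw + ridge * np.trace(sw + np.eye(n_pc_eff)) / n_pc_eff * np.eye(n_pc_eff)

    eigval, eigvec = eigh(sb, sw_reg)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    w = eigvec[:, :n_da]  # discriminant directions in PC space

    sample_scores = scores @ w
    # back-project to feature space, square and normalize per axis
    feat_dir = rot @ w  # p x n_da
    contrib = feat_dir ** 2
    colsum = contrib.sum(axis=0)
    colsum[colsum == 0] = 1.0
    contrib = contrib / colsum

    if feature_names is None:
        feature_names = [f"F{j}" for j in range(p)]
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    loadings = pd.DataFrame(
        contrib, index=feature_names, columns=[f"LD{a + 1}" for a in range(n_da)]
    )
    return DapcResult(
        n_pc_retained=n_pc_eff,
        n_da=n_da,
        samples=list(samples),
        sample_scores=sample_scores,
        loadings=loadings,
        group_assignment=groups,
        separation=float(eigval[0]) if len(eigval) else 0.0,
    )


def select_influential(
    res: DapcResult, percentile: float = 0.90, rule: str = "percentile"
) -> list[str]:
    """Loci whose maximum per-axis loading clears a threshold.

    ``rule="percentile"`` (default): threshold is the empirical
    ``percentile`` quantile of the max-loadings; ties at the boundary
    are all included.  ``rule="above_mean"``: threshold-free variant
    keeping every locus whose max loading exceeds the mean max loading
    (typically selects a much larger set).
    """
    if not 0.0 < percentile < 1.0:
        raise AnalysisError("percentile must be in (0, 1)")
    max_load = res.loadings.max(axis=1)
    if len(max_load) < 10:
        log.warning("fewer than 10 features; percentile threshold is coarse")
    if rule == "percentile":
        thr = float(np.quantile(max_load.to_numpy(), percentile))
    elif rule == "above_mean":
        thr = float(max_load.mean())
    else:
        raise AnalysisError(f"unknown selection rule {rule!r}")
    selected = max_load.index[max_load.to_numpy() >= thr].tolist()
    log.info(
        "selected %d/%d influential loci (%.1f%%) by %s rule",
        len(selected), len(max_load), 100.0 * len(selected) / len(max_load), rule,
    )
    return selected
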