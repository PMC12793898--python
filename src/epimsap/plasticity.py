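"""Phenotype-epigenotype plasticity coupling.

The statistic asks whether groups of animals that shifted more in
methylation space also shifted more in physiological performance.  For
each pair of sample groups (same site across seasons, or transplant
phases), it takes

* the Euclidean distance between the groups' centroids in PCoA space of
  the methylation profiles (epigenetic plasticity), and
* the absolute difference of the groups' mean log(x+1)-transformed
  righting times (phenotypic plasticity),

and rank-correlates the two distance lists with Spearman's rho.  With
few pairs the p-value comes from the exact permutation distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._spearman import spearman
from .errors import AnalysisError
from .multivariate import group_centroids
from .types import OrdinationResult, PhenotypeTable, SampleMetadata

log = logging.getLogger(__name__)

PAIRINGS = ("WITHIN_SITE_ACROSS_SEASON", "ACROSS_STATUS", "ALL_PAIRS")


@dataclass
class PlasticityCoupling:
    pairs: pd.DataFrame  # pair, epi_distance, pheno_distance
    rho: float
    p: float
    n_pairs: int
    defined: bool  # False when too few pairs for a correlation

    def as_dict(self) -> dict:
        return {"rho": self.rho, "p": self.p, "n_pairs": self.n_pairs, "defined": self.defined}


def _group_pairs(groups: list[str], pairing: str) -> list[tuple[str, str]]:
    """Enumerate the group pairs whose centroid distances are compared.

    Groups are "site:level" labels.  WITHIN_SITE_ACROSS_SEASON and
    ACROSS_STATUS pair groups sharing a site; ALL_PAIRS compares every
    group combination (the cross-site variant).
    """
    if pairing == "ALL_PAIRS":
        return list(combinations(sorted(groups), 2))
    pairs = []
    by_site: dict[str, list[str]] = {}
    for g in sorted(groups):
        site = g.split(":")[0]
        by_site.setdefault(site, []).append(g)
    for site, members in by_site.items():
        pairs.extend(combinations(members, 2))
    return pairs


def coupling(
    epi_ord: OrdinationResult,
    pheno: PhenotypeTable,
    meta: SampleMetadata,
    pairing: str = "WITHIN_SITE_ACROSS_SEASON",
    n_axes: int | None = None,
) -> PlasticityCoupling:
    """Correlate per-group-pair epigenetic and phenotypic centroid shifts.

    ``n_axes`` limits the PCoA axes entering the epigenetic distance
    (default: all positive-eigenvalue axes).  Righting times are
    log(x+1)-transformed before group means are taken.  With fewer than
    3 pairs the correlation is undefined and flagged, never silently NaN.
    """
    if pairing not in PAIRINGS:
        raise AnalysisError(f"unknown pairing {pairing!r}; expected one of {PAIRINGS}")
    factor = "site:season" if pairing == "WITHIN_SITE_ACROSS_SEASON" else (
        "site:status" if pairing == "ACROSS_STATUS" else "site:season"
    )
    groups = meta.factor(factor, epi_ord.samples)
    counts = pd.Series(groups).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise AnalysisError(f"groups with < 2 samples: {sorted(small.index)}")

    coords = epi_ord.coordinates
    if n_axes is not None:
        coords = coords[:, :n_axes]
    sub_ord = OrdinationResult(
        kind=epi_ord.kind, samples=epi_ord.samples, coordinates=coords,
        eigenvalues=epi_ord.eigenvalues, explained=epi_ord.explained,
    )
    centroids = group_centroids(sub_ord, groups)

    ph = pheno.aligned(epi_ord.samples)
    log_right = np.log1p(ph["righting_time"].to_numpy(dtype=float))
    pheno_mean = {
        g: float(log_right[groups == g].mean()) for g in pd.unique(groups)
    }

    rows = []
    for a, b in _group_pairs(list(pd.unique(groups)), pairing):
        rows.append({
            "pair": f"{a}|{b}",
            "epi_distance": float(np.linalg.norm(centroids[a] - centroids[b])),
            "pheno_distance": abs(pheno_mean[a] - pheno_mean[b]),
        })
    table = pd.DataFrame(rows)

    if len(table) < 3:
        log.warning("only %d group pair(s); coupling rho undefined", len(table))
        return PlasticityCoupling(
            pairs=table, rho=float("nan"), p=float("nan"),
            n_pairs=len(table), defined=False,
        )
    rho, p = spearman(table["epi_distance"], table["pheno_distance"])
    defined = np.isfinite(rho)
    if not defined:
        log.warning("constant distance list; coupling rho undefined")
    return PlasticityCoupling(pairs=table, rho=rho, p=p, n_pairs=len(table), defined=bool(defined))
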