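"""Epigenetic heterogeneity: Shannon diversity and state-frequency profiles.

Shannon's index is computed per methylation-susceptible locus over the
frequency distribution of the four methylation states among scored
(non-MISSING) samples, H = -sum_s p_s log p_s.  With four states, H lies
in [0, ln 4] in the default natural-log base.  The headline summary is
the mean +/- SD of H across MSL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .types import MISSING, STATE_LABELS, STATE_ORDER, SampleMetadata, StateMatrix

log = logging.getLogger(__name__)


@dataclass
class DiversityReport:
    per_locus_H: pd.Series  # locus -> Shannon index
    mean_H: float
    sd_H: float
    n_loci: int

    def as_dict(self) -> dict:
        return {"mean_H": self.mean_H, "sd_H": self.sd_H, "n_loci": self.n_loci}


def _state_counts(sm: StateMatrix, locus_idx: np.ndarray) -> np.ndarray:
    """Counts (n_loci x 4) of each state among scored samples."""
    states = sm.states[:, locus_idx]
    return np.stack([(states == s).sum(axis=0) for s in STATE_ORDER], axis=1)


def shannon_index(freqs: np.ndarray, base: float = math.e) -> float:
    """Shannon index of a frequency vector (zeros contribute nothing)."""
    p = np.asarray(freqs, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(base))


def shannon_per_locus(
    sm: StateMatrix, base: float = math.e, over: str = "loci"
) -> DiversityReport:
    """Shannon diversity of methylation states, per MSL.

    ``over`` selects the aggregation axis for the mean +/- SD summary:
    ``"loci"`` (default) averages per-locus H across MSL; ``"samples"``
    computes H per sample across its MSL states and averages across
    samples.  Loci (or samples) with fewer than 2 scored cells are
    excluded with a warning.
    """
    idx = sm.msl_indices()
    if over == "loci":
        counts = _state_counts(sm, idx)
        labels = [sm.loci[j] for j in idx]
    elif over == "samples":
        states = sm.states[:, idx]
        counts = np.stack([(states == s).sum(axis=1) for s in STATE_ORDER], axis=1)
        labels = list(sm.samples)
    else:
        raise AnalysisError(f"unknown aggregation {over!r}; use 'loci' or 'samples'")

    totals = counts.sum(axis=1)
    valid = totals >= 2
    if (~valid).any():
        log.warning("%d %s with < 2 scored cells excluded from H", int((~valid).sum()), over)
    h = np.array([
        shannon_index(counts[i] / totals[i], base=base) for i in np.flatnonzero(valid)
    ])
    series = pd.Series(h, index=[labels[i] for i in np.flatnonzero(valid)], name="H")
    return DiversityReport(
        per_locus_H=series,
        mean_H=float(series.mean()) if len(series) else float("nan"),
        sd_H=float(series.std(ddof=1)) if len(series) > 1 else 0.0,
        n_loci=len(series),
    )


def state_frequencies(
    sm: StateMatrix,
    meta: SampleMetadata,
    group_by: str,
    polymorphic_only: bool = True,
) -> pd.DataFrame:
    """Mean state fractions per group with a standard error across loci.

    For each group of samples, each MSL contributes the fraction of its
    scored samples in each of the four states; the table reports the
    mean of those fractions across loci and their SE.  Within a locus
    and group the four fractions sum to 1 over scored cells, so the
    group means do too.
    """
    idx = sm.msl_indices()
    if polymorphic_only and sm.is_polymorphic is not None:
        idx = np.flatnonzero(sm.is_msl & sm.is_polymorphic)
    groups = meta.factor(group_by, sm.samples)
    rows = []
    for g in pd.unique(groups):
        members = np.flatnonzero(groups == g)
        states = sm.states[np.ix_(members, idx)]
        scored = (states != MISSING).sum(axis=0).astype(float)
        ok = scored > 0
        if not ok.any():
            log.warning("group %r has no scored cells; excluded", g)
            continue
        for s in STATE_ORDER:
            frac = (states == s).sum(axis=0)[ok] / scored[ok]
            rows.append({
                "group": g,
                "state": STATE_LABELS[s],
                "mean_fraction": float(frac.mean()),
                "se": float(frac.std(ddof=1) / np.sqrt(len(frac))) if len(frac) > 1 else 0.0,
            })
    return pd.DataFrame(rows)
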