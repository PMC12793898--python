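"""MSAP scoring: peak filtering, fragment binning and methylation-state calls.

The scoring rules follow common MSAP practice for two-digest
(HpaII/MspI) fingerprints:

* peaks are kept when 50 bp <= size <= 1500 bp and intensity is
  strictly above 40 RFU (both windows configurable);
* surviving peaks are binned into fixed-width fragment-size loci;
* loci present in fewer than 15% of samples are discarded;
* the joint presence pattern (HpaII, MspI) maps to one of four states:
  (1,1) non-methylated NMT, (1,0) hemimethylated HMM, (0,1) internal
  cytosine methylation ICM, and (0,0) scored conservatively as
  hypermethylation HPM;
* only methylation-susceptible loci (MSL) — loci whose methylated-state
  frequency exceeds an error threshold (default 5%) — are retained for
  the downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .types import (
    FragmentMatrix,
    HMM,
    HPM,
    ICM,
    METHYLATED_STATES,
    MISSING,
    NMT,
    PeakTable,
    STATE_ORDER,
    StateMatrix,
)

log = logging.getLogger(__name__)

# Defaults for peak filtering and MSL partitioning.
SIZE_MIN = 50.0
SIZE_MAX = 1500.0
RFU_MIN = 40.0
BIN_WIDTH = 1.0
MIN_PREVALENCE = 0.15
METH_THRESHOLD = 0.05


def binarize_peaks(
    peaks: PeakTable,
    size_min: float = SIZE_MIN,
    size_max: float = SIZE_MAX,
    rfu_min: float = RFU_MIN,
    bin_width: float = BIN_WIDTH,
) -> FragmentMatrix:
    """Filter peaks and bin them into a per-digest presence/absence matrix.

    A locus bin is 1 for a sample/digest iff at least one surviving peak
    falls in the bin.  Bins are ``bin_width`` wide and anchored at
    integer multiples of the width, so the default 1 bp bins collect
    fragment sizes by their integer part.  Bins empty in every
    sample/digest are not materialised.  A sample seen in either digest
    gets explicit 0 rows in both layers (a sample entirely absent from
    one digest layer is left 0, not NA, because the export format does
    not distinguish "no peaks survived" from "not run").
    """
    if size_min >= size_max:
        raise ConfigError("size_min must be < size_max")
    if rfu_min < 0:
        raise ConfigError("rfu_min must be nonnegative")
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")

    df = peaks.data
    kept = df[(df["size"] >= size_min) & (df["size"] <= size_max) & (df["height"] > rfu_min)]
    if df.empty:
        log.warning("empty peak table; returning empty fragment matrix")
    samples = sorted(df["sample_id"].unique())

    bins = np.floor(kept["size"].to_numpy() / bin_width).astype(int) if len(kept) else np.array([], int)
    unique_bins = sorted(set(bins.tolist()))
    loci = [f"L{int(b * bin_width)}" for b in unique_bins]
    bin_index = {b: j for j, b in enumerate(unique_bins)}
    sample_index = {s: i for i, s in enumerate(samples)}

    layers = {
        "HPA": np.zeros((len(samples), len(loci))),
        "MSP": np.zeros((len(samples), len(loci))),
    }
    for (sid, digest), b in zip(zip(kept["sample_id"], kept["digest"]), bins):
        layers[digest][sample_index[sid], bin_index[b]] = 1.0

    fm = FragmentMatrix(samples=samples, loci=loci, hpa=layers["HPA"], msp=layers["MSP"])
    log.info(
        "binarized %d/%d peaks into %d loci x %d samples",
        len(kept), len(df), fm.n_loci, fm.n_samples,
    )
    return fm


def filter_prevalence(
    fm: FragmentMatrix,
    min_prevalence: float = MIN_PREVALENCE,
    per_digest: bool = False,
) -> FragmentMatrix:
    """Retain loci present (in either digest) in >= ``min_prevalence`` of samples.

    With ``per_digest=True`` the criterion must hold separately in each
    digest layer instead of on the pooled presence.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ConfigError("min_prevalence must be in [0, 1]")
    n = fm.n_samples
    if n == 0:
        return fm
    hpa = np.nan_to_num(fm.hpa)
    msp = np.nan_to_num(fm.msp)
    if per_digest:
        keep = (hpa.sum(axis=0) / n >= min_prevalence) & (msp.sum(axis=0) / n >= min_prevalence)
    else:
        pooled = np.maximum(hpa, msp)
        keep = pooled.sum(axis=0) / n >= min_prevalence
    idx = np.flatnonzero(keep)
    return FragmentMatrix(
        samples=fm.samples,
        loci=[fm.loci[j] for j in idx],
        hpa=fm.hpa[:, idx],
        msp=fm.msp[:, idx],
    )


def classify_states(fm: FragmentMatrix) -> StateMatrix:
    """Map each (HpaII, MspI) presence pair to a methylation state.

    (1,1) -> NMT, (1,0) -> HMM, (0,1) -> ICM, (0,0) -> HPM; any NA in
    either digest -> MISSING.  Total on {0, 1, NA}^2.
    """
    hpa, msp = fm.hpa, fm.msp
    states = np.full(hpa.shape, MISSING, dtype=np.int8)
    scored = ~np.isnan(hpa) & ~np.isnan(msp)
    h = hpa == 1.0
    m = msp == 1.0
    states[scored & h & m] = NMT
    states[scored & h & ~m] = HMM
    states[scored & ~h & m] = ICM
    states[scored & ~h & ~m] = HPM
    return StateMatrix(samples=list(fm.samples), loci=list(fm.loci), states=states)


@dataclass
class MslReport:
    n_loci: int
    n_msl: int
    n_polymorphic_msl: int
    pct_polymorphic_msl: float

    def as_dict(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "n_msl": self.n_msl,
            "n_polymorphic_msl": self.n_polymorphic_msl,
            "pct_polymorphic_msl": self.pct_polymorphic_msl,
        }


def partition_msl(
    sm: StateMatrix, meth_threshold: float = METH_THRESHOLD
) -> tuple[StateMatrix, MslReport]:
    """Flag methylation-susceptible and polymorphic loci.

    A locus is MSL iff the fraction of non-MISSING samples in a
    methylated state (HMM, ICM or HPM) strictly exceeds
    ``meth_threshold``.  A locus is polymorphic iff it shows >= 2
    distinct non-MISSING states.  Loci scored in no sample are excluded
    from both classes.
    """
    if not 0.0 <= meth_threshold <= 1.0:
        raise ConfigError("meth_threshold must be in [0, 1]")
    states = sm.states
    scored = states != MISSING
    n_scored = scored.sum(axis=0)
    methylated = np.isin(states, METHYLATED_STATES) & scored
    with np.errstate(invalid="ignore", divide="ignore"):
        meth_frac = np.where(n_scored > 0, methylated.sum(axis=0) / np.maximum(n_scored, 1), 0.0)
    is_msl = (meth_frac > meth_threshold) & (n_scored > 0)
    if (n_scored == 0).any():
        log.warning("%d loci scored in no sample; excluded from MSL", int((n_scored == 0).sum()))

    is_poly = np.zeros(sm.n_loci, dtype=bool)
    for j in range(sm.n_loci):
        col = states[scored[:, j], j]
        is_poly[j] = len(np.unique(col)) >= 2

    out = StateMatrix(
        samples=list(sm.samples), loci=list(sm.loci), states=states,
        is_msl=is_msl, is_polymorphic=is_poly,
    )
    n_msl = int(is_msl.sum())
    n_poly_msl = int((is_msl & is_poly).sum())
    report = MslReport(
        n_loci=sm.n_loci,
        n_msl=n_msl,
        n_polymorphic_msl=n_poly_msl,
        pct_polymorphic_msl=100.0 * n_poly_msl / n_msl if n_msl else 0.0,
    )
    log.info(
        "MSL partition: %d/%d loci MSL, %d polymorphic (%.1f%%)",
        n_msl, sm.n_loci, n_poly_msl, report.pct_polymorphic_msl,
    )
    return out, report


def encode_matrix(sm: StateMatrix, scheme: str = "METH_BINARY") -> np.ndarray:
    """Encode the MSL columns numerically for distance/ordination work.

    ``METH_BINARY``: one column per MSL, 1 if the state is methylated
    (HMM/ICM/HPM) else 0.  ``ONEHOT4``: four indicator columns per MSL
    in the fixed order NMT, HMM, ICM, HPM.  MISSING cells are imputed
    with the feature-wise mean of the scored cells.
    """
    idx = sm.msl_indices()
    states = sm.states[:, idx]
    missing = states == MISSING

    if scheme == "METH_BINARY":
        x = np.isin(states, METHYLATED_STATES).astype(float)
    elif scheme == "ONEHOT4":
        cols = [(states == s).astype(float) for s in STATE_ORDER]
        x = np.stack(cols, axis=2).reshape(states.shape[0], -1)
        missing = np.repeat(missing, len(STATE_ORDER), axis=1)
    else:
        raise ConfigError(f"unknown encoding scheme {scheme!r}")

    if missing.any():
        x = x.copy()
        x[missing] = np.nan
        col_mean = np.nanmean(x, axis=0)
        col_mean = np.nan_to_num(col_mean)  # all-missing feature -> 0
        fill = np.where(np.isnan(x), np.broadcast_to(col_mean, x.shape), x)
        n_imp = int(missing.sum())
        log.info("mean-imputed %d missing cells during %s encoding", n_imp, scheme)
        x = fill
    return x
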