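"""Ecological field computations for the reef-monitoring design.

Covers the study-defined derived quantities: sediment-trap deposition
rate, molar N:P nutrient-limitation status, hydroclimatic season
assignment, urchin size classes, belt-transect density, chained monthly
survival rates for caged cohorts, and the rank correlation between test
diameter and righting time.

Boundary conventions (documented because they matter for counts):
size classes are small < 40 mm, medium 40-60 mm inclusive at both ends,
large > 60 mm; N:P <= 16 is nitrogen-limited, 16 < ratio <= 22 is the
transition zone, > 22 phosphorus-limited; the dry season is
January-April and the wet season May-November (December is outside the
sampling design and rejected).
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np

from ._spearman import spearman
from .errors import AnalysisError

log = logging.getLogger(__name__)

spearman_corr = spearman  # diameter-vs-righting correlation entry point


def sedimentation_rate(mass_mg: float, aperture_diameter_cm: float = 6.4, days: float = 1.0) -> float:
    """Deposition rate in mg·cm^-2·day^-1 from a cylindrical trap.

    rate = mass / (pi * (diameter/2)^2 * days); mass 0 is a valid empty
    trap.
    """
    if aperture_diameter_cm <= 0:
        raise AnalysisError("aperture diameter must be positive")
    if days <= 0:
        raise AnalysisError("deployment duration must be positive")
    if mass_mg < 0:
        raise AnalysisError("sediment mass cannot be negative")
    area = math.pi * (aperture_diameter_cm / 2.0) ** 2
    return mass_mg / (area * days)


N_LIMITED, TRANSITION, P_LIMITED = "N_LIMITED", "TRANSITION", "P_LIMITED"


def np_status(total_n: float, total_p: float) -> tuple[str, float]:
    """Nutrient-limitation class and the molar N:P ratio.

    <= 16 (Redfield) nitrogen limitation; (16, 22] transition toward
    phosphorus limitation; > 22 phosphorus limitation.
    """
    if total_p <= 0:
        raise AnalysisError("total P must be positive to form an N:P ratio")
    ratio = total_n / total_p
    if ratio <= 16.0:
        return N_LIMITED, ratio
    if ratio <= 22.0:
        return TRANSITION, ratio
    return P_LIMITED, ratio


def season_of(date: dt.date) -> str:
    """DRY for January-April, WET for May-November; December undefined."""
    if date.month == 12:
        raise AnalysisError("December is outside the defined seasonal scheme")
    return "DRY" if date.month <= 4 else "WET"


def size_class(test_diameter_mm: float) -> str:
    """SMALL < 40 mm, MEDIUM 40-60 mm (inclusive), LARGE > 60 mm."""
    if test_diameter_mm <= 0:
        raise AnalysisError("test diameter must be positive")
    if test_diameter_mm < 40.0:
        return "SMALL"
    if test_diameter_mm <= 60.0:
        return "MEDIUM"
    return "LARGE"


def transect_density(count: int, transect_area_m2: float = 20.0) -> float:
    """Individuals per square metre on a belt transect."""
    if transect_area_m2 <= 0:
        raise AnalysisError("transect area must be positive")
    if count < 0:
        raise AnalysisError("count cannot be negative")
    return count / transect_area_m2


def density_summary(counts: list[int], transect_area_m2: float = 20.0) -> tuple[float, float]:
    """Mean and SD of density over replicate transects."""
    dens = np.array([transect_density(c, transect_area_m2) for c in counts])
    sd = float(dens.std(ddof=1)) if len(dens) > 1 else 0.0
    return float(dens.mean()), sd


@dataclass
class SurvivalRecord:
    month: int
    n_initial: int
    n_final: int

    @property
    def sr(self) -> float:
        return self.n_final / self.n_initial


@dataclass
class SurvivalSeries:
    records: list[SurvivalRecord]
    mean_sr: float
    terminated: bool  # True when the cohort hit zero before the last census

    @property
    def terminal_fraction(self) -> float:
        if not self.records:
            return float("nan")
        return self.records[-1].n_final / self.records[0].n_initial


def survival_series(counts: list[int]) -> SurvivalSeries:
    """Chained monthly survival rates SR_t = N_t / N_{t-1}.

    Each month's initial count is the previous month's final count, so
    the product of the monthly SRs equals the terminal fraction.  An
    increase between censuses is impossible in a closed cage and only
    warned about; a zero count terminates the series.
    """
    if len(counts) < 2:
        raise AnalysisError("need at least two monthly counts")
    if counts[0] <= 0:
        raise AnalysisError("initial count must be positive")
    records = []
    terminated = False
    for month, (ni, nf) in enumerate(zip(counts[:-1], counts[1:]), start=1):
        if nf > ni:
            log.warning("count increased %d -> %d at month %d (recruitment in a cage?)", ni, nf, month)
        records.append(SurvivalRecord(month=month, n_initial=ni, n_final=nf))
        if nf == 0:
            terminated = month < len(counts) - 1
            break
    mean_sr = float(np.mean([r.sr for r in records]))
    return SurvivalSeries(records=records, mean_sr=mean_sr, terminated=terminated)
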