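"""Core in-memory containers for MSAP data.

The pipeline moves data through three central containers:

``PeakTable``
    Validated capillary-electrophoresis peak calls (one row per peak)
    for the two isoschizomer digests, HpaII (``HPA``) and MspI (``MSP``).

``FragmentMatrix``
    Per-digest binary presence/absence of fragment-size bins
    (samples x loci), with ``NaN`` marking unscored cells.  ``NaN`` is
    deliberately distinct from 0: absence in *both* digests is an
    informative methylation pattern (hypermethylation), whereas an
    unscored cell is simply unknown.

``StateMatrix``
    Per sample x locus methylation state derived from the joint
    HpaII/MspI presence pattern, plus per-locus flags marking
    methylation-susceptible loci (MSL) and polymorphism.

States are stored as small integer codes; ``state_labels`` maps codes to
the conventional four-letter names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

# Methylation-state codes.  The pair notation is (HpaII, MspI) presence.
MISSING = -1
NMT = 0  # 1/1 non-methylated: fragment amplified in both digests
HMM = 1  # 1/0 hemimethylated: HpaII only
ICM = 2  # 0/1 internal cytosine methylation: MspI only
HPM = 3  # 0/0 hypermethylated (conservative reading of double absence)

STATE_LABELS = {NMT: "NMT", HMM: "HMM", ICM: "ICM", HPM: "HPM", MISSING: "MISSING"}
LABEL_TO_STATE = {v: k for k, v in STATE_LABELS.items()}
STATE_ORDER = (NMT, HMM, ICM, HPM)  # fixed order for one-hot encodings and tables

METHYLATED_STATES = (HMM, ICM, HPM)

DIGESTS = ("HPA", "MSP")

PEAK_COLUMNS = ("sample_id", "digest", "size", "height")


@dataclass
class PeakTable:
    """Validated peak calls: sample_id, digest, size (bp), height (RFU), dye."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"peak table missing required column(s): {missing}")
        bad_digest = set(self.data["digest"]) - set(DIGESTS)
        if bad_digest:
            raise FormatError(f"unknown digest value(s): {sorted(bad_digest)}")
        if (self.data["size"] <= 0).any():
            raise FormatError("fragment sizes must be positive")
        if (self.data["height"] < 0).any():
            raise FormatError("peak heights must be nonnegative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())


@dataclass
class FragmentMatrix:
    """Binary presence/absence per digest; NaN encodes unscored cells."""

    samples: list[str]
    loci: list[str]
    hpa: np.ndarray  # (n_samples, n_loci) float, values in {0, 1, nan}
    msp: np.ndarray

    def __post_init__(self) -> None:
        self.hpa = np.asarray(self.hpa, dtype=float)
        self.msp = np.asarray(self.msp, dtype=float)
        shape = (len(self.samples), len(self.loci))
        if self.hpa.shape != shape or self.msp.shape != shape:
            raise FormatError(
                f"digest layers must both be {shape}; got {self.hpa.shape} / {self.msp.shape}"
            )
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicated sample_id in fragment matrix")
        if len(set(self.loci)) != len(self.loci):
            raise FormatError("duplicated locus id in fragment matrix")
        for layer in (self.hpa, self.msp):
            vals = layer[~np.isnan(layer)]
            if not np.isin(vals, (0.0, 1.0)).all():
                raise FormatError("fragment matrix cells must be 0, 1 or NA")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "HPA": pd.DataFrame(self.hpa, index=self.samples, columns=self.loci),
            "MSP": pd.DataFrame(self.msp, index=self.samples, columns=self.loci),
        }


@dataclass
class StateMatrix:
    """Methylation states (integer codes) with per-locus MSL/polymorphism flags.

    ``is_msl`` / ``is_polymorphic`` are ``None`` until
    :func:`epimsap.msap_scoring.partition_msl` has been applied.
    """

    samples: list[str]
    loci: list[str]
    states: np.ndarray  # (n_samples, n_loci) int8, MISSING = -1
    is_msl: np.ndarray | None = None
    is_polymorphic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.samples), len(self.loci)):
            raise FormatError("state matrix shape inconsistent with sample/locus lists")
        if not np.isin(self.states, (MISSING, NMT, HMM, ICM, HPM)).all():
            raise FormatError("invalid state code in state matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def msl_indices(self) -> np.ndarray:
        if self.is_msl is None:
            raise FormatError("MSL partition not computed; run partition_msl first")
        return np.flatnonzero(self.is_msl)

    def to_frame(self) -> pd.DataFrame:
        """Labelled representation (strings) used for CSV output."""
        labels = np.vectorize(STATE_LABELS.get)(self.states)
        return pd.DataFrame(labels, index=self.samples, columns=self.loci)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample dissimilarities with zero diagonal."""

    samples: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.samples)
        if self.d.shape != (n, n):
            raise FormatError("distance matrix must be square over the sample list")
        if not np.isfinite(self.d).all():
            raise FormatError("distance matrix contains non-finite entries")
        if (self.d < -1e-12).any():
            raise FormatError("distances must be nonnegative")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise FormatError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise FormatError("distance matrix diagonal must be zero")
        self.d = 0.5 * (self.d + self.d.T)
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass
class OrdinationResult:
    """Sample coordinates with eigenvalues and explained-variance fractions."""

    kind: str  # PCOA | RDA | DBRDA | DAPC
    samples: list[str]
    coordinates: np.ndarray  # (n_samples, n_axes)
    eigenvalues: np.ndarray
    explained: np.ndarray  # fraction per axis

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class SampleMetadata:
    """Sample annotations: site, season, timepoint, transplant status."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "site")
    SITES = ("TG", "PM", "AH", "PS")
    SEASONS = ("DRY", "WET")
    STATUSES = ("BT", "DA", "AA", "TGC", "PSC", "NONE")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing required column(s): {missing}")
        if self.data["sample_id"].duplicated().any():
            dups = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicated sample_id in metadata: {sorted(set(dups))}")
        if "season" in self.data.columns:
            bad = set(self.data["season"].dropna()) - set(self.SEASONS)
            if bad:
                raise FormatError(f"unknown season value(s): {sorted(bad)}")
        if "status" in self.data.columns:
            bad = set(self.data["status"].dropna()) - set(self.STATUSES)
            if bad:
                raise FormatError(f"unknown status value(s): {sorted(bad)}")

    def factor(self, name: str, samples: list[str]) -> np.ndarray:
        """Return the factor levels for ``samples`` in order.

        Composite factors may be requested as e.g. ``"site:season"``.
        """
        indexed = self.data.set_index("sample_id")
        missing = [s for s in samples if s not in indexed.index]
        if missing:
            raise FormatError(f"samples absent from metadata: {missing[:5]}")
        parts = name.split(":")
        for p in parts:
            if p not in indexed.columns:
                raise FormatError(f"metadata has no column {p!r}")
        sub = indexed.loc[samples]
        if len(parts) == 1:
            return sub[parts[0]].to_numpy()
        return np.array([":".join(str(sub.loc[s, p]) for p in parts) for s in samples])


@dataclass
class PhenotypeTable:
    """Per-sample righting time (s) and test diameter (mm)."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "righting_time", "test_diameter")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"phenotype table missing column(s): {missing}")
        if self.data["sample_id"].duplicated().any():
            raise FormatError("duplicated sample_id in phenotype table")
        if (self.data["righting_time"] <= 0).any():
            raise FormatError("righting_time must be positive")
        if (self.data["test_diameter"] <= 0).any():
            raise FormatError("test_diameter must be positive")

    def aligned(self, samples: list[str]) -> pd.DataFrame:
        indexed = self.data.set_index("sample_id")
        missing = [s for s in samples if s not in indexed.index]
        if missing:
            raise FormatError(f"samples absent from phenotype table: {missing[:5]}")
        return indexed.loc[samples]
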