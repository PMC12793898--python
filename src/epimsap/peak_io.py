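"""Readers and writers for the tabular formats the pipeline touches.

Genotyping-software exports vary in column naming (``Sample Name`` vs
``sample``, ``Size`` vs ``bp`` ...), so :func:`read_peak_table` accepts a
*dialect* mapping from the canonical field names to the column headers
actually present.  All files are UTF-8; the delimiter is comma by
default with tab auto-detection.

Readers never silently drop rows: malformed rows raise a
:class:`~epimsap.errors.FormatError` naming the offending line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .types import (
    DIGESTS,
    FragmentMatrix,
    LABEL_TO_STATE,
    PeakTable,
    PhenotypeTable,
    SampleMetadata,
    StateMatrix,
)

log = logging.getLogger(__name__)

#: Default column-name dialect for peak tables (GeneMapper-style headers).
DEFAULT_DIALECT = {
    "sample_id": "Sample",
    "digest": "Digest",
    "size": "Size",
    "height": "Height",
    "dye": "Dye",
}


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    return pd.read_csv(path, sep=_sniff_sep(path), dtype=str)


def read_peak_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    digest: str | None = None,
) -> PeakTable:
    """Read a capillary-electrophoresis peak export into a :class:`PeakTable`.

    Parameters
    ----------
    path
        CSV/TSV file with one row per called peak.
    dialect
        Mapping from canonical names (``sample_id``, ``digest``, ``size``,
        ``height``, ``dye``) to the file's column headers.  Keys absent
        from the mapping fall back to :data:`DEFAULT_DIALECT`.
    digest
        If the export holds a single digest and has no digest column,
        pass ``"HPA"`` or ``"MSP"`` here.
    """
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    raw = _read_table(path)

    required = ["sample_id", "size", "height"] if digest else ["sample_id", "digest", "size", "height"]
    for field in required:
        if dia[field] not in raw.columns:
            raise FormatError(
                f"peak table {path} missing required column {dia[field]!r} (field {field})"
            )

    out = pd.DataFrame({"sample_id": raw[dia["sample_id"]].astype(str)})
    if digest:
        if digest not in DIGESTS:
            raise FormatError(f"unknown digest {digest!r}; expected one of {DIGESTS}")
        out["digest"] = digest
    else:
        out["digest"] = raw[dia["digest"]].astype(str).str.upper()

    for field in ("size", "height"):
        converted = pd.to_numeric(raw[dia[field]], errors="coerce")
        bad = converted.isna() & raw[dia[field]].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after header
            raise FormatError(
                f"non-numeric {field} value {raw.loc[bad.idxmax(), dia[field]]!r} "
                f"at line {line} of {path}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise FormatError(f"missing {field} value at line {line} of {path}")
        out[field] = converted.astype(float)

    if dia.get("dye") in raw.columns:
        out["dye"] = raw[dia["dye"]].astype(str)

    table = PeakTable(out)
    log.info("read %d peaks for %d samples from %s", len(table), len(table.samples), path)
    return table


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def merge_peak_tables(*tables: PeakTable) -> PeakTable:
    """Concatenate per-digest exports into a single table."""
    return PeakTable(pd.concat([t.data for t in tables], ignore_index=True))


def _parse_binary_frame(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    def convert(cell: object) -> float:
        if pd.isna(cell) or str(cell).strip().upper() in ("NA", "NAN", ""):
            return np.nan
        if str(cell).strip() in ("0", "0.0"):
            return 0.0
        if str(cell).strip() in ("1", "1.0"):
            return 1.0
        raise FormatError(f"cell value {cell!r} in {path} not in {{0, 1, NA}}")

    return df.map(convert)


def read_fragment_matrix(
    path: str | Path,
    msp_path: str | Path | None = None,
) -> FragmentMatrix:
    """Read a pre-binarized fragment presence/absence matrix.

    Two layouts are supported:

    * a single file with a ``digest`` column (first two columns
      ``sample_id``, ``digest``; remaining columns loci), or
    * two per-digest files (``path`` = HpaII layer, ``msp_path`` = MspI
      layer), each with sample rows and locus columns.
    """
    if msp_path is not None:
        frames = {}
        for name, p in (("HPA", path), ("MSP", msp_path)):
            raw = _read_table(p).set_index(_read_table(p).columns[0])
            if raw.index.duplicated().any():
                raise FormatError(f"duplicated sample_id in {p}")
            frames[name] = _parse_binary_frame(raw, p)
        hpa, msp = frames["HPA"], frames["MSP"]
        if list(hpa.index) != list(msp.index) or list(hpa.columns) != list(msp.columns):
            raise FormatError("per-digest files disagree on samples or loci")
        return FragmentMatrix(
            samples=list(hpa.index), loci=list(hpa.columns),
            hpa=hpa.to_numpy(), msp=msp.to_numpy(),
        )

    raw = _read_table(path)
    first_cols = [c.lower() for c in raw.columns[:2]]
    if "digest" not in first_cols:
        raise FormatError(
            f"{path}: single-file layout needs a 'digest' column; "
            "for per-digest files pass msp_path as well"
        )
    raw.columns = ["sample_id", "digest"] + list(raw.columns[2:])
    layers = {}
    for name, chunk in raw.groupby(raw["digest"].str.upper()):
        if name not in DIGESTS:
            raise FormatError(f"unknown digest {name!r} in {path}")
        sub = chunk.drop(columns="digest").set_index("sample_id")
        if sub.index.duplicated().any():
            raise FormatError(f"duplicated sample_id for digest {name} in {path}")
        layers[name] = _parse_binary_frame(sub, path)
    if set(layers) != set(DIGESTS):
        raise FormatError(f"{path}: both HPA and MSP layers are required")
    hpa, msp = layers["HPA"], layers["MSP"]
    msp = msp.loc[hpa.index, hpa.columns]
    return FragmentMatrix(
        samples=list(hpa.index), loci=list(hpa.columns),
        hpa=hpa.to_numpy(), msp=msp.to_numpy(),
    )


def write_fragment_matrix(fm: FragmentMatrix, path: str | Path) -> None:
    """Single-file layout with a digest column; NA cells written as 'NA'."""
    frames = fm.to_frames()
    rows = []
    for digest in DIGESTS:
        df = frames[digest].copy()
        df.insert(0, "digest", digest)
        df.insert(0, "sample_id", df.index)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    for c in fm.loci:
        out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def read_state_matrix(path: str | Path) -> StateMatrix:
    """Read a labelled state matrix (samples x loci of NMT/HMM/ICM/HPM/MISSING)."""
    raw = _read_table(path)
    raw = raw.set_index(raw.columns[0])
    try:
        states = raw.map(lambda v: LABEL_TO_STATE[str(v).strip().upper()]).to_numpy()
    except KeyError as exc:
        raise FormatError(f"unknown state label {exc.args[0]!r} in {path}") from exc
    return StateMatrix(samples=list(raw.index), loci=list(raw.columns), states=states)


def write_state_matrix(sm: StateMatrix, path: str | Path) -> None:
    df = sm.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path)


def read_metadata(path: str | Path) -> SampleMetadata:
    raw = _read_table(path)
    return SampleMetadata(raw)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    raw = _read_table(path)
    for col in ("righting_time", "test_diameter"):
        if col in raw.columns:
            raw[col] = pd.to_numeric(raw[col], errors="raise")
    return PhenotypeTable(raw)


def read_environment(path: str | Path) -> pd.DataFrame:
    """Environmental records; numeric columns coerced, others left as text."""
    raw = _read_table(path)
    for col in raw.columns:
        if col not in ("site", "date", "sample_id"):
            raw[col] = pd.to_numeric(raw[col], errors="coerce")
    return raw
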