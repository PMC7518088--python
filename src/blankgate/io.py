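"""Tabular input/output for the low-biomass amplicon QC pipeline.

All four tables (OTU counts, taxonomy, sample metadata, qPCR crossing
points) travel as tab-delimited UTF-8 text with a single header row;
lines starting with ``#`` are ignored.  The first column is always the
identifier column, matching flat tables exported from QIIME2.  Parsed
tables are validated into the typed containers below, so downstream
code never has to re-check units, signs or identifier uniqueness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("blankgate")

__all__ = [
    "TableValidationError",
    "OtuTable",
    "TaxonomyTable",
    "Metadata",
    "CpTable",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_cp_table",
    "write_cp_table",
    "read_standard_curve_points",
]

BLANK_TYPES = ("filtered-water", "unused-filter")

_TRUE_TOKENS = {"true", "t", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n"}


class TableValidationError(ValueError):
    """An input table violates one of the pipeline's structural invariants."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                       keep_default_na=False, na_values=[""])


def _parse_bool(token, *, context: str) -> bool:
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise TableValidationError(f"{context}: cannot interpret {token!r} as a boolean")


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

class OtuTable:
    """A samples x OTUs abundance matrix with an explicit unit tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are OTUs, values non-negative.
    unit : {"counts", "percent"}
        ``counts`` for raw read counts, ``percent`` for rows scaled to
        sum to 100.  The unit is carried explicitly and never guessed by
        downstream stages.
    """

    def __init__(self, data: pd.DataFrame, unit: str = "counts"):
        if unit not in ("counts", "percent"):
            raise TableValidationError(f"unknown unit {unit!r}")
        data = data.copy()
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dups}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate OTU ids: {dups}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise TableValidationError(
                f"non-finite value at sample {data.index[i]!r}, OTU {data.columns[j]!r}")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative value at sample {data.index[i]!r}, OTU {data.columns[j]!r}")
        if unit == "percent":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 100.0) > 1e-6
            if bad.any():
                sid = data.index[np.argmax(bad)]
                raise TableValidationError(
                    f"percent-unit row for sample {sid!r} sums to "
                    f"{sums[np.argmax(bad)]:.6f}, expected 100")
        self.data = data.astype(float) if unit == "percent" else data
        self.unit = unit

    # -- basic protocol ----------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def sample_row(self, sample_id) -> np.ndarray:
        return self.data.loc[sample_id].to_numpy(dtype=float)

    def select_samples(self, sample_ids: Iterable) -> "OtuTable":
        return OtuTable(self.data.loc[list(sample_ids)], unit=self.unit)

    def __eq__(self, other):
        return (isinstance(other, OtuTable) and self.unit == other.unit
                and self.data.equals(other.data))

    def __repr__(self):
        n, m = self.data.shape
        return f"OtuTable({n} samples x {m} OTUs, unit={self.unit!r})"

    def to_biom_json(self, path) -> None:
        """Write a minimal BIOM-style (sparse, JSON) export. Write-only."""
        values = self.values()
        rows, cols = np.nonzero(values)
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "sparse",
            "matrix_element_type": "int" if self.unit == "counts" else "float",
            "shape": [len(self.otu_ids), len(self.sample_ids)],
            # BIOM convention: rows are observations (OTUs)
            "rows": [{"id": str(o), "metadata": None} for o in self.otu_ids],
            "columns": [{"id": str(s), "metadata": None} for s in self.sample_ids],
            "data": [[int(c), int(r), values[r, c].item()] for r, c in zip(rows, cols)],
        }
        Path(path).write_text(json.dumps(doc))


def read_otu_table(path, orientation: str = "samples", unit: str | None = None) -> OtuTable:
    """Read a TSV abundance table into an :class:`OtuTable`.

    ``orientation`` declares what the rows of the file are: ``"samples"``
    (default) or ``"otus"`` (the table is transposed on read).  Square
    tables are never transposed silently — the caller's orientation
    argument is authoritative.  The unit is inferred as ``"counts"``
    when every value is integral, else ``"percent"``, unless ``unit``
    overrides the inference.
    """
    if orientation not in ("samples", "otus"):
        raise TableValidationError(f"orientation must be 'samples' or 'otus', got {orientation!r}")
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise TableValidationError(f"{path}: need an id column plus at least one data column")
    idcol = raw.columns[0]
    if raw[idcol].isna().any():
        raise TableValidationError(f"{path}: empty id cell")
    frame = raw.set_index(idcol)
    if frame.isna().any().any():
        r = frame.index[frame.isna().any(axis=1)][0]
        raise TableValidationError(f"{path}: missing value in row {r!r} (ragged table?)")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise TableValidationError(f"{path}: non-numeric abundance value ({exc})") from exc
    if orientation == "otus":
        frame = frame.T
    frame.index.name = None
    frame.columns.name = None
    if unit is None:
        values = frame.to_numpy()
        unit = "counts" if np.allclose(values, np.round(values), atol=0) else "percent"
    if unit == "counts":
        frame = frame.round().astype(np.int64)
    return OtuTable(frame, unit=unit)


def _format_value(v) -> str:
    if float(v) == int(v):
        return str(int(v))
    return format(float(v), ".6g")


def write_otu_table(table: OtuTable, path, orientation: str = "samples") -> None:
    """Write an :class:`OtuTable` as TSV (inverse of :func:`read_otu_table`)."""
    frame = table.data if orientation == "samples" else table.data.T
    idname = "sample_id" if orientation == "samples" else "otu_id"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(idname + "\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        for rid, row in zip(frame.index, frame.to_numpy()):
            fh.write(str(rid) + "\t" + "\t".join(_format_value(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxonomyTable:
    """OTU id -> ordered lineage (domain ... species; missing ranks allowed)."""

    lineages: dict

    def __post_init__(self):
        # dict construction already enforces unique otu ids; normalise values
        self.lineages = {str(k): tuple(v) for k, v in self.lineages.items()}

    def lineage(self, otu_id) -> tuple:
        return self.lineages[str(otu_id)]

    def __len__(self):
        return len(self.lineages)

    def __contains__(self, otu_id):
        return str(otu_id) in self.lineages


def read_taxonomy(path) -> TaxonomyTable:
    """Read a TSV taxonomy table (otu_id + one column per rank, or a single
    semicolon-delimited lineage column)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise TableValidationError(f"{path}: need otu_id plus lineage column(s)")
    idcol = raw.columns[0]
    if raw[idcol].duplicated().any():
        dups = raw[idcol][raw[idcol].duplicated()].tolist()
        raise TableValidationError(f"{path}: duplicate otu ids {dups}")
    lineages = {}
    if raw.shape[1] == 2:
        for _, row in raw.iterrows():
            lineage = tuple(p.strip() for p in str(row.iloc[1]).split(";"))
            lineages[row[idcol]] = lineage
    else:
        for _, row in raw.iterrows():
            lineages[row[idcol]] = tuple(
                "" if pd.isna(v) else str(v) for v in row.iloc[1:])
    return TaxonomyTable(lineages)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

class Metadata:
    """Per-sample metadata: filtered volume, batch, blank and lab-QC flags.

    Wraps a DataFrame indexed by ``sample_id`` with columns ``volume_ml``
    (integer mL), ``carboy_id``, ``is_blank``, ``blank_type`` and
    ``lab_amplified``.  ``lab_amplified`` is the laboratory's own
    amplification verdict — an *input*, never computed here (the lab's
    internal threshold is opaque).  ``None`` means unknown.

    Invariants: blanks have volume 0 mL and a ``blank_type``; non-blanks
    have neither.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.duplicated().any():
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids in metadata: {dups}")
        for sid, row in frame.iterrows():
            if row["is_blank"]:
                if row["volume_ml"] != 0:
                    raise TableValidationError(
                        f"blank sample {sid!r} has nonzero volume {row['volume_ml']} mL")
                if row["blank_type"] is None:
                    raise TableValidationError(f"blank sample {sid!r} lacks blank_type")
                if row["blank_type"] not in BLANK_TYPES:
                    raise TableValidationError(
                        f"sample {sid!r}: unknown blank_type {row['blank_type']!r} "
                        f"(expected one of {BLANK_TYPES})")
            elif row["blank_type"] is not None:
                raise TableValidationError(
                    f"non-blank sample {sid!r} carries blank_type {row['blank_type']!r}")
            if not (0 <= row["volume_ml"] <= 1000):
                raise TableValidationError(
                    f"sample {sid!r}: volume {row['volume_ml']} mL outside 0-1000")
        self.frame = frame

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def blank_ids(self) -> list:
        return list(self.frame.index[self.frame["is_blank"]])

    @property
    def nonblank_ids(self) -> list:
        return list(self.frame.index[~self.frame["is_blank"]])

    def is_blank(self, sample_id) -> bool:
        return bool(self.frame.at[sample_id, "is_blank"])

    def volume(self, sample_id) -> int:
        return int(self.frame.at[sample_id, "volume_ml"])

    def lab_amplified(self, sample_id):
        return self.frame.at[sample_id, "lab_amplified"]

    @property
    def has_lab_flags(self) -> bool:
        return self.frame["lab_amplified"].notna().all()

    def __len__(self):
        return len(self.frame)

    def __contains__(self, sample_id):
        return sample_id in self.frame.index

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "Metadata":
        rows = []
        for rec in records:
            rows.append({
                "sample_id": str(rec["sample_id"]),
                "volume_ml": int(rec["volume_ml"]),
                "carboy_id": str(rec.get("carboy_id", "")) or None,
                "is_blank": bool(rec["is_blank"]),
                "blank_type": rec.get("blank_type") or None,
                "lab_amplified": rec.get("lab_amplified", None),
            })
        frame = pd.DataFrame(rows).set_index("sample_id")
        frame.index.name = None
        return cls(frame)


def read_metadata(path) -> Metadata:
    """Read sample metadata TSV (required columns: sample_id, volume_mL,
    is_blank; optional: carboy_id, blank_type, lab_amplified)."""
    raw = _read_tsv(path)
    cols = {c.lower(): c for c in raw.columns}
    for req in ("sample_id", "volume_ml", "is_blank"):
        if req not in cols:
            raise TableValidationError(f"{path}: missing required column {req!r}")
    records = []
    for _, row in raw.iterrows():
        sid = str(row[cols["sample_id"]]).strip()
        try:
            volume = int(float(row[cols["volume_ml"]]))
        except (TypeError, ValueError) as exc:
            raise TableValidationError(f"{path}: sample {sid!r}: bad volume") from exc
        is_blank = _parse_bool(row[cols["is_blank"]], context=f"sample {sid!r} is_blank")
        blank_type = None
        if "blank_type" in cols and not pd.isna(row[cols["blank_type"]]):
            token = str(row[cols["blank_type"]]).strip().lower()
            blank_type = token or None
        lab = None
        if "lab_amplified" in cols and not pd.isna(row[cols["lab_amplified"]]):
            lab = _parse_bool(row[cols["lab_amplified"]],
                              context=f"sample {sid!r} lab_amplified")
        carboy = None
        if "carboy_id" in cols and not pd.isna(row[cols["carboy_id"]]):
            carboy = str(row[cols["carboy_id"]]).strip() or None
        records.append({"sample_id": sid, "volume_ml": volume, "is_blank": is_blank,
                        "blank_type": blank_type, "lab_amplified": lab,
                        "carboy_id": carboy})
    return Metadata.from_records(records)


def write_metadata(metadata: Metadata, path) -> None:
    frame = metadata.frame.copy()
    out = pd.DataFrame({
        "sample_id": frame.index,
        "volume_mL": frame["volume_ml"].astype(int).to_numpy(),
        "is_blank": [str(bool(v)).lower() for v in frame["is_blank"]],
        "blank_type": ["" if v is None else v for v in frame["blank_type"]],
        "carboy_id": ["" if v is None else v for v in frame["carboy_id"]],
        "lab_amplified": ["" if pd.isna(v) else str(bool(v)).lower()
                          for v in frame["lab_amplified"]],
    })
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# qPCR crossing-point table
# ---------------------------------------------------------------------------

class CpTable:
    """Per-sample qPCR crossing-point (Cp) replicates.

    Each sample carries >= 1 finite Cp value in cycles, within (0, 60).
    Typically three replicates per sample; failed replicates are simply
    absent.
    """

    def __init__(self, replicates: Mapping[str, Sequence[float]]):
        store = {}
        for sid, reps in replicates.items():
            reps = [float(r) for r in reps]
            if len(reps) == 0:
                raise TableValidationError(f"sample {sid!r} has no surviving Cp replicates")
            for r in reps:
                if not np.isfinite(r) or not (0.0 < r < 60.0):
                    raise TableValidationError(
                        f"sample {sid!r}: Cp {r} outside the plausible cycle range (0, 60)")
            if str(sid) in store:
                raise TableValidationError(f"duplicate sample id {sid!r} in Cp table")
            store[str(sid)] = reps
        if not store:
            raise TableValidationError("Cp table is empty")
        self.replicates = store

    @property
    def sample_ids(self) -> list:
        return list(self.replicates)

    def __contains__(self, sample_id):
        return str(sample_id) in self.replicates

    def __getitem__(self, sample_id) -> list:
        return list(self.replicates[str(sample_id)])

    def __len__(self):
        return len(self.replicates)


def read_cp_table(path) -> CpTable:
    """Read a triplicate Cp TSV (sample_id + one column per replicate).

    Empty cells mark failed replicates; they are dropped with a logged
    warning.  A sample with no surviving replicate is an error.
    """
    raw = _read_tsv(path)
    cols = {c.lower(): c for c in raw.columns}
    if "sample_id" not in cols:
        raise TableValidationError(f"{path}: missing required column 'sample_id'")
    rep_cols = [c for c in raw.columns if c != cols["sample_id"]]
    if not rep_cols:
        raise TableValidationError(f"{path}: no replicate columns")
    replicates = {}
    for _, row in raw.iterrows():
        sid = str(row[cols["sample_id"]]).strip()
        reps = []
        for c in rep_cols:
            v = row[c]
            if pd.isna(v) or str(v).strip() == "":
                logger.warning("Cp table: sample %s replicate %s missing; dropped", sid, c)
                continue
            try:
                reps.append(float(v))
            except ValueError as exc:
                raise TableValidationError(
                    f"{path}: sample {sid!r}, column {c!r}: non-numeric Cp {v!r}") from exc
        if not reps:
            raise TableValidationError(f"{path}: sample {sid!r} has zero surviving replicates")
        if sid in replicates:
            raise TableValidationError(f"{path}: duplicate sample id {sid!r}")
        replicates[sid] = reps
    return CpTable(replicates)


def write_cp_table(cp: CpTable, path) -> None:
    n_rep = max(len(v) for v in cp.replicates.values())
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\t" + "\t".join(f"cp{i + 1}" for i in range(n_rep)) + "\n")
        for sid, reps in cp.replicates.items():
            cells = [format(r, ".6g") for r in reps] + [""] * (n_rep - len(reps))
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_standard_curve_points(path) -> list:
    """Read standard-curve calibration points: columns log10_copies, cp."""
    raw = _read_tsv(path)
    cols = {c.lower(): c for c in raw.columns}
    for req in ("log10_copies", "cp"):
        if req not in cols:
            raise TableValidationError(f"{path}: missing required column {req!r}")
    points = []
    for _, row in raw.iterrows():
        points.append((float(row[cols["log10_copies"]]), float(row[cols["cp"]])))
    return points
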