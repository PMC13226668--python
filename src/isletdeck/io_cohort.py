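"""Readers/writers for the on-disk formats the pipeline touches and a validated cohort container.

Count matrices follow the 10x convention: a Matrix Market triplet file
(``matrix.mtx``) with ``features.tsv`` / ``barcodes.tsv`` sidecars, one
directory per library.  Internally everything is 0-based; the Matrix Market
files keep their standard 1-based coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


class GlycemicState(str, Enum):
    ND = "ND"
    PD = "PD"
    T2D = "T2D"


# ADA prediabetes band: HbA1c 5.7-6.4 %
PD_BAND = (5.7, 6.4)


def state_from_hba1c(hba1c: float, band: tuple[float, float] = PD_BAND) -> GlycemicState:
    """Assign a glycemic state from HbA1c using the prediabetes band."""
    lo, hi = band
    if hba1c < lo:
        return GlycemicState.ND
    if hba1c <= hi:
        return GlycemicState.PD
    return GlycemicState.T2D


@dataclass
class CountsMatrix:
    """Sparse gene x droplet UMI counts for one library."""

    values: sp.csc_matrix  # genes x droplets
    gene_ids: list[str]
    barcode_ids: list[str]
    library_id: str = ""

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        if self.values.shape[0] != len(self.gene_ids):
            raise FormatError(
                f"row count {self.values.shape[0]} != len(gene_ids) {len(self.gene_ids)}"
            )
        if self.values.shape[1] != len(self.barcode_ids):
            raise FormatError(
                f"column count {self.values.shape[1]} != len(barcode_ids) {len(self.barcode_ids)}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            raise FormatError("duplicate barcode identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative counts are not allowed")
        if self.values.nnz and not np.allclose(self.values.data, np.round(self.values.data)):
            raise FormatError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_droplets(self) -> int:
        return self.values.shape[1]

    def column_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def equals(self, other: "CountsMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.barcode_ids == other.barcode_ids
            and (self.values != other.values).nnz == 0
        )


@dataclass
class FloatMatrix:
    """Float-valued matrix variant used for decontaminated counts."""

    values: sp.csc_matrix
    gene_ids: list[str]
    barcode_ids: list[str]
    library_id: str = ""


@dataclass
class DonorRecord:
    donor_id: str
    state: GlycemicState
    hba1c: float
    age: float
    bmi: float
    sex: str  # F / M
    ancestry: str
    chemistry: str  # V2 / V3

    def __post_init__(self) -> None:
        if self.hba1c <= 0:
            raise ValueError(f"donor {self.donor_id}: hba1c must be > 0")
        self.state = GlycemicState(self.state)


CELL_TABLE_COLUMNS = [
    "barcode_id",
    "library_id",
    "donor_id",
    "nFEA",
    "nUMI",
    "pMT",
    "doublet",
    "filtered",
    "reasons",
    "cluster",
    "cell_type",
]


def new_cell_table(barcodes: Sequence[str], library_id: str) -> pd.DataFrame:
    """Fresh per-droplet record table for one library."""
    df = pd.DataFrame(
        {
            "barcode_id": list(barcodes),
            "library_id": library_id,
            "donor_id": pd.Series([None] * len(barcodes), dtype=object),
            "nFEA": 0,
            "nUMI": 0,
            "pMT": 0.0,
            "doublet": False,
            "filtered": False,
            "reasons": [[] for _ in barcodes],
            "cluster": pd.Series([None] * len(barcodes), dtype=object),
            "cell_type": pd.Series([None] * len(barcodes), dtype=object),
        }
    )
    return df


def flag_cells(cells: pd.DataFrame, mask: np.ndarray, reason: str) -> pd.DataFrame:
    """Mark cells filtered with a machine-readable reason (idempotent per reason)."""
    cells = cells.copy()
    idx = np.flatnonzero(np.asarray(mask))
    cells.loc[cells.index[idx], "filtered"] = True
    for i in idx:
        lst = cells.iat[i, cells.columns.get_loc("reasons")]
        if reason not in lst:
            cells.iat[i, cells.columns.get_loc("reasons")] = lst + [reason]
    return cells


@dataclass
class CohortBundle:
    """All per-library matrices plus donor and cell metadata."""

    raw: dict[str, CountsMatrix]
    filtered: dict[str, CountsMatrix]
    cells: pd.DataFrame
    donors: list[DonorRecord]
    multiplex_map: dict[str, list[str]]  # library_id -> donor_ids

    def donor_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "donor_id": d.donor_id,
                    "state": d.state.value,
                    "hba1c": d.hba1c,
                    "age": d.age,
                    "bmi": d.bmi,
                    "sex": d.sex,
                    "ancestry": d.ancestry,
                    "chemistry": d.chemistry,
                }
                for d in self.donors
            ]
        )


# ---------------------------------------------------------------------------
# Matrix Market bundles


def read_counts_mtx(dir_path: str | Path) -> CountsMatrix:
    """Read a 10x-style directory (matrix.mtx + features.tsv + barcodes.tsv)."""
    dir_path = Path(dir_path)
    mtx_path = dir_path / "matrix.mtx"
    feat_path = dir_path / "features.tsv"
    bc_path = dir_path / "barcodes.tsv"
    for p in (mtx_path, feat_path, bc_path):
        if not p.exists():
            raise FormatError(f"missing file: {p}")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"{mtx_path}: malformed Matrix Market file ({exc})") from exc
    genes = feat_path.read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g]
    barcodes = [b.split("\t")[0] for b in bc_path.read_text().splitlines() if b]
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{mtx_path}: header declares {mat.shape[0]} genes but {feat_path} lists {len(genes)}"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: header declares {mat.shape[1]} barcodes but {bc_path} lists {len(barcodes)}"
        )
    return CountsMatrix(sp.csc_matrix(mat), genes, barcodes, library_id=dir_path.name)


def write_counts_mtx(m: CountsMatrix, dir_path: str | Path) -> None:
    """Write a 10x-style directory; triplets sorted by (column, row); 64-bit safe."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    # CSC ordering is (column, row); mmwrite emits in that order.
    vals = sp.csc_matrix(m.values)
    vals.sort_indices()
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), vals.astype(np.int64), field="integer")
    (dir_path / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (dir_path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in m.barcode_ids))


# ---------------------------------------------------------------------------
# Tabular readers


DONOR_SCHEMA = {
    "donor_id": str,
    "hba1c": float,
    "age": float,
    "bmi": float,
    "sex": str,
    "ancestry": str,
    "chemistry": str,
}


def read_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    """Read a TSV with a header row, coercing columns per ``schema``.

    Unknown columns are preserved as strings; a missing required column or an
    unparseable cell raises :class:`FormatError` naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns and c != "state"]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = df.copy()
    for col, typ in schema.items():
        if col not in df.columns:
            continue
        if typ is float or typ is int:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.values)[0]) + 2  # 1-based incl. header
                raise FormatError(f"{path}: unparseable {col!r} value at row {row}")
            out[col] = coerced.astype(typ)
    return out


def read_donor_table(path: str | Path, band: tuple[float, float] = PD_BAND) -> list[DonorRecord]:
    """Read a donor TSV; states auto-assigned from HbA1c when the column is absent."""
    df = read_table(path, {**DONOR_SCHEMA, "state": str})
    records = []
    for _, row in df.iterrows():
        state = row["state"] if "state" in df.columns and row.get("state") else None
        if state is None:
            state = state_from_hba1c(float(row["hba1c"]), band).value
        records.append(
            DonorRecord(
                donor_id=row["donor_id"],
                state=GlycemicState(state),
                hba1c=float(row["hba1c"]),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                sex=row["sex"],
                ancestry=row["ancestry"],
                chemistry=row["chemistry"],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Validation


def validate_cohort(b: CohortBundle) -> list[str]:
    """Return a list of invariant violations; an empty list means valid."""
    report: list[str] = []
    donor_ids = {d.donor_id for d in b.donors}
    for lib, dlist in b.multiplex_map.items():
        if not dlist:
            report.append(f"library {lib}: no donors mapped")
        for d in dlist:
            if d not in donor_ids:
                report.append(f"library {lib}: unknown donor_id {d}")
    for lib, filt in b.filtered.items():
        if lib not in b.raw:
            report.append(f"library {lib}: filtered matrix without raw matrix")
            continue
        raw_bcs = set(b.raw[lib].barcode_ids)
        extra = [bc for bc in filt.barcode_ids if bc not in raw_bcs]
        if extra:
            report.append(
                f"library {lib}: {len(extra)} filtered barcode(s) absent from raw (e.g. {extra[0]})"
            )
    # Cell table checks
    cells = b.cells
    if len(cells):
        if ((cells["pMT"] < 0) | (cells["pMT"] > 100)).any():
            report.append("cell table: pMT outside [0, 100]")
        if (cells["nFEA"] > cells["nUMI"]).any():
            report.append("cell table: nFEA > nUMI for some cells")
        dup = cells.duplicated(subset=["library_id", "barcode_id"])
        if dup.any():
            report.append("cell table: duplicate (library_id, barcode_id) keys")
        for lib in cells["library_id"].unique():
            if lib not in b.raw:
                report.append(f"cell table: unknown library {lib}")
    return report
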