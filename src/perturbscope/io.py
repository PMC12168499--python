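"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
* All intervals are 0-based half-open throughout (BED convention).
* TSV outputs are UTF-8, tab-separated, with a single header line
  prefixed ``#``.
* Sparse count matrices travel as a MatrixMarket triplet directory:
  ``matrix.mtx`` (1-based coordinate format, features x cells as in the
  common single-cell layout) plus ``barcodes.tsv`` and ``features.tsv``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from perturbscope.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MODALITIES = ("RNA", "ATAC")
TARGET_CLASSES = ("TF", "NT", "SAFE")
CONTROL_CLASSES = ("NT", "SAFE")


# ---------------------------------------------------------------------------
# FeatureMatrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Sparse cell x feature non-negative integer counts for one modality."""

    modality: str
    counts: sp.csr_matrix
    barcodes: np.ndarray
    features: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.features = np.asarray(self.features, dtype=object)
        n_cells, n_features = self.counts.shape
        if len(self.barcodes) != n_cells:
            raise ValidationError(
                f"{len(self.barcodes)} barcodes for a matrix with {n_cells} cells"
            )
        if len(self.features) != n_features:
            raise ValidationError(
                f"{len(self.features)} features for a matrix with {n_features} columns"
            )
        if len(set(self.barcodes)) != n_cells:
            raise ValidationError("duplicate cell barcodes")
        if len(set(self.features)) != n_features:
            raise ValidationError("duplicate feature identifiers")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative counts in matrix")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer counts in matrix")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def feature_index(self) -> dict:
        return {f: i for i, f in enumerate(self.features)}

    def subset_cells(self, mask_or_idx) -> "FeatureMatrix":
        idx = np.asarray(mask_or_idx)
        return FeatureMatrix(
            self.modality, self.counts[idx], self.barcodes[idx], self.features
        )


def write_matrix(m: FeatureMatrix, path: str) -> None:
    """Write a FeatureMatrix as matrix.mtx + barcodes.tsv + features.tsv.

    The .mtx is stored features x cells (the conventional orientation),
    with integer values and 1-based coordinates.
    """
    os.makedirs(path, exist_ok=True)
    mat = sp.coo_matrix(m.counts.T).astype(np.int64)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), mat, field="integer")
    with open(os.path.join(path, "barcodes.tsv"), "w", encoding="utf-8") as fh:
        for bc in m.barcodes:
            fh.write(f"{bc}\n")
    with open(os.path.join(path, "features.tsv"), "w", encoding="utf-8") as fh:
        for ft in m.features:
            fh.write(f"{ft}\n")


def read_matrix(path: str, modality: str) -> FeatureMatrix:
    """Read a MatrixMarket triplet directory written by :func:`write_matrix`."""
    mtx_path = os.path.join(path, "matrix.mtx")
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # scipy raises ValueError on bad headers
        raise FormatError(f"{mtx_path}: not a readable MatrixMarket file ({exc})") from exc
    barcodes = _read_lines(os.path.join(path, "barcodes.tsv"))
    features = _read_lines(os.path.join(path, "features.tsv"))
    n_features, n_cells = mat.shape
    if len(features) != n_features:
        raise FormatError(
            f"{path}: features.tsv has {len(features)} rows but matrix has {n_features} feature rows"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"{path}: barcodes.tsv has {len(barcodes)} rows but matrix has {n_cells} cell columns"
        )
    counts = sp.csr_matrix(mat.T)
    if counts.data.size and (np.any(counts.data < 0) or not np.allclose(counts.data, np.round(counts.data))):
        raise FormatError(f"{mtx_path}: matrix entries must be non-negative integers")
    try:
        return FeatureMatrix(modality, counts.astype(np.int64), np.array(barcodes, dtype=object), np.array(features, dtype=object))
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_lines(path: str) -> list:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Intervals (BED) and gene annotations
# ---------------------------------------------------------------------------

INTERVAL_COLUMNS = ["chrom", "start", "end", "name"]


def validate_intervals(df: pd.DataFrame, what: str = "intervals") -> pd.DataFrame:
    """Validate and sort an interval table (0-based half-open)."""
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValidationError(f"{what}: missing column {col!r}")
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValidationError(
            f"{what}: empty or inverted interval at row {bad[0]}: "
            f"{row['chrom']}:{row['start']}-{row['end']}"
        )
    if np.any(df["start"].to_numpy() < 0):
        raise ValidationError(f"{what}: negative start coordinate")
    if "name" in df.columns and df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise ValidationError(f"{what}: duplicate identifier {dup!r}")
    out = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return out


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3+ file into a sorted interval table.

    Columns beyond the first four are preserved as ``extra_<i>``.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else f"iv_{lineno}"
            row = {"chrom": parts[0], "start": start, "end": end, "name": name}
            for i, extra in enumerate(parts[4:]):
                row[f"extra_{i}"] = extra
            rows.append(row)
    df = pd.DataFrame(rows, columns=None)
    if df.empty:
        df = pd.DataFrame(columns=INTERVAL_COLUMNS)
    return validate_intervals(df, what=path)


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in INTERVAL_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_table(path: str, schema: dict) -> pd.DataFrame:
    """Read a TSV whose header line may be prefixed ``#``; cast per schema.

    ``schema`` maps required column names to dtypes; extra columns are
    preserved untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col, dtype in schema.items():
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: column {col!r} not castable to {dtype}") from exc
    return df


def write_table(df: pd.DataFrame, path: str) -> None:
    """Write a TSV with a single '#'-prefixed header line."""
    out = df.copy()
    if len(out.columns):
        out.columns = [f"#{out.columns[0]}"] + list(out.columns[1:])
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Guide assignments and genotype calls
# ---------------------------------------------------------------------------

GUIDE_SCHEMA = {"cell": str, "guide_id": str, "target": str, "target_class": str}


def validate_guides(df: pd.DataFrame) -> pd.DataFrame:
    if df["cell"].duplicated().any():
        dup = df.loc[df["cell"].duplicated(), "cell"].iloc[0]
        raise ValidationError(f"guide table: more than one guide for cell {dup!r}")
    bad_class = set(df["target_class"]) - set(TARGET_CLASSES)
    if bad_class:
        raise ValidationError(f"guide table: unknown target_class {sorted(bad_class)}")
    tf_rows = df[df["target_class"] == "TF"]
    if (tf_rows["target"].astype(str).str.len() == 0).any():
        raise ValidationError("guide table: TF row with empty target symbol")
    return df.reset_index(drop=True)


def read_guides(path: str) -> pd.DataFrame:
    return validate_guides(read_table(path, GUIDE_SCHEMA))


def align_guides(m: FeatureMatrix, guides: pd.DataFrame) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Restrict a matrix to cells present in the guide table (and vice versa).

    Cells without a detected guide are dropped with a logged count, mirroring
    screens where guide identity is recovered in only part of the cells.
    """
    assigned = set(guides["cell"])
    keep = np.array([bc in assigned for bc in m.barcodes])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d/%d cells without guide assignment", n_drop, m.n_cells)
    sub = m.subset_cells(np.flatnonzero(keep))
    order = {bc: i for i, bc in enumerate(sub.barcodes)}
    g = guides[guides["cell"].isin(order)].copy()
    g["_ord"] = g["cell"].map(order)
    g = g.sort_values("_ord").drop(columns="_ord").reset_index(drop=True)
    return sub, g


GENOTYPE_SCHEMA = {"cell": str, "guide_id": str, "edited": str, "amplicon": str}


def read_genotypes(path: str) -> pd.DataFrame:
    df = read_table(path, GENOTYPE_SCHEMA)
    df["edited"] = df["edited"].map({"True": True, "False": False, "1": True, "0": False})
    if df["edited"].isna().any():
        raise FormatError(f"{path}: 'edited' column must be boolean")
    return df


# ---------------------------------------------------------------------------
# GWAS-side tables
# ---------------------------------------------------------------------------

CREDIBLE_SET_SCHEMA = {
    "trait": str,
    "set_id": str,
    "snp_id": str,
    "chrom": str,
    "pos": np.int64,
    "pip": np.float64,
}

SNP_H2_SCHEMA = {"snp_id": str, "chrom": str, "pos": np.int64, "h2_contribution": np.float64}


def read_credible_sets(path: str, one_based: bool = False) -> pd.DataFrame:
    df = read_table(path, CREDIBLE_SET_SCHEMA)
    if one_based:
        df["pos"] = df["pos"] - 1
    if ((df["pip"] <= 0) | (df["pip"] > 1)).any():
        raise ValidationError(f"{path}: PIP values must lie in (0, 1]")
    sums = df.groupby(["trait", "set_id"])["pip"].sum()
    if (sums > 1 + 1e-9).any():
        bad = sums[sums > 1 + 1e-9].index[0]
        raise ValidationError(f"{path}: PIP sum exceeds 1 for credible set {bad}")
    return df


def read_snp_h2(path: str) -> pd.DataFrame:
    df = read_table(path, SNP_H2_SCHEMA)
    if (df["h2_contribution"] < 0).any():
        raise ValidationError(f"{path}: negative per-SNP heritability contribution")
    return df


GENE_SCHEMA = {"gene_id": str, "chrom": str, "tss": np.int64, "strand": str}


def read_genes(path: str) -> pd.DataFrame:
    df = read_table(path, GENE_SCHEMA)
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene_id")
    bad = set(df["strand"]) - {"+", "-"}
    if bad:
        raise ValidationError(f"{path}: invalid strand value(s) {sorted(bad)}")
    return df.sort_values(["chrom", "tss"], kind="stable").reset_index(drop=True)
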