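"""Readers and writers for the formats the pipeline touches.

Disk conventions follow the 10x triplet layout: a Matrix Market coordinate
file (genes x nuclei, 1-based indices on disk), a features TSV and a barcodes
TSV with one record per line.  All in-memory indices are 0-based.  Gzipped
inputs (``.gz`` suffix) are accepted transparently.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

DEFAULT_REPORTER_IDS = ("eGFP", "tdTomato")
DEFAULT_MITO_PREFIX = "mt-"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class CountMatrix:
    """Sparse genes x nuclei count matrix with annotation tables.

    Attributes
    ----------
    counts
        CSR matrix of nonnegative integers, shape (n_genes, n_nuclei).
    genes
        DataFrame with columns ``gene_id``, ``symbol``, ``is_mito``,
        ``is_reporter``; one row per matrix row, in matrix order.
    nuclei
        DataFrame with columns ``barcode``, ``sample_id`` and optionally
        ``exon_fraction``; one row per matrix column.
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    nuclei: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.genes):
            raise FormatError(
                f"matrix has {self.counts.shape[0]} rows but gene table has "
                f"{len(self.genes)} entries"
            )
        if self.counts.shape[1] != len(self.nuclei):
            raise FormatError(
                f"matrix has {self.counts.shape[1]} columns but nucleus table "
                f"has {len(self.nuclei)} entries"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be nonnegative integers")
        self.counts.data = self.counts.data.astype(np.int64)
        pairs = list(zip(self.nuclei["barcode"], self.nuclei["sample_id"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(barcode, sample_id) pairs must be unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    def subset_nuclei(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[:, idx],
            genes=self.genes.copy(),
            nuclei=self.nuclei.iloc[idx].reset_index(drop=True),
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx, :],
            genes=self.genes.iloc[idx].reset_index(drop=True),
            nuclei=self.nuclei.copy(),
        )


def concat_nuclei(cms: Sequence[CountMatrix]) -> CountMatrix:
    """Concatenate samples column-wise; gene tables must agree on gene_id."""
    if not cms:
        raise ValueError("need at least one CountMatrix")
    ref = list(cms[0].genes["gene_id"])
    for cm in cms[1:]:
        if list(cm.genes["gene_id"]) != ref:
            raise ValueError("gene tables differ between samples")
    return CountMatrix(
        counts=sp.hstack([cm.counts for cm in cms], format="csr"),
        genes=cms[0].genes.copy(),
        nuclei=pd.concat([cm.nuclei for cm in cms], ignore_index=True),
    )


def _open_text(path) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_counts_triplet(
    matrix_path,
    features_path,
    barcodes_path,
    sample_id: str,
    reporter_ids: Sequence[str] = DEFAULT_REPORTER_IDS,
    mito_prefix: str = DEFAULT_MITO_PREFIX,
    exon_fraction: Sequence[float] | None = None,
) -> CountMatrix:
    """Read a 10x-style MTX triplet into a :class:`CountMatrix`.

    ``is_mito`` is set by a case-insensitive gene-symbol prefix match and
    ``is_reporter`` by exact gene-ID membership in ``reporter_ids``.
    Gene and barcode order on disk is preserved.
    """
    path = os.fspath(matrix_path)
    opener = gzip.open if path.endswith(".gz") else open
    try:
        with opener(path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # mmread raises bare ValueError on bad headers
        raise FormatError(f"cannot parse Matrix Market file {path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.data.size and (np.any(mat.data < 0) or np.any(mat.data != np.round(mat.data))):
        raise ValueError("matrix entries must be nonnegative integers")

    features = _read_feature_lines(features_path)
    barcodes = [line[0] for line in _read_tsv_lines(barcodes_path)]

    if len(features) != mat.shape[0]:
        raise FormatError(
            f"features file has {len(features)} rows but matrix has "
            f"{mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"barcodes file has {len(barcodes)} rows but matrix has "
            f"{mat.shape[1]} columns"
        )
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcodes file")

    gene_ids = [f[0] for f in features]
    symbols = [f[1] for f in features]
    reporter_set = set(reporter_ids)
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "is_mito": [s.lower().startswith(mito_prefix.lower()) for s in symbols],
            "is_reporter": [g in reporter_set for g in gene_ids],
        }
    )
    nuclei = pd.DataFrame({"barcode": barcodes, "sample_id": sample_id})
    if exon_fraction is not None:
        ef = np.asarray(exon_fraction, dtype=float)
        if len(ef) != len(barcodes):
            raise FormatError("exon_fraction length does not match barcodes")
        _check_unit_interval(ef, "exon_fraction")
        nuclei["exon_fraction"] = ef
    return CountMatrix(counts=mat.tocsr(), genes=genes, nuclei=nuclei)


def _read_feature_lines(path) -> list[tuple[str, str]]:
    out = []
    for fields in _read_tsv_lines(path):
        gene_id = fields[0]
        symbol = fields[1] if len(fields) > 1 else fields[0]
        out.append((gene_id, symbol))
    return out


def _read_tsv_lines(path) -> list[list[str]]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def write_counts_triplet(cm: CountMatrix, out_dir) -> dict[str, Path]:
    """Write ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv`` under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), cm.counts.tocoo(), field="integer")
    with open(paths["features"], "w", encoding="utf-8") as fh:
        for _, row in cm.genes.iterrows():
            fh.write(f"{row.gene_id}\t{row.symbol}\tGene Expression\n")
    with open(paths["barcodes"], "w", encoding="utf-8") as fh:
        for bc in cm.nuclei["barcode"]:
            fh.write(f"{bc}\n")
    return paths


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str] = field(default_factory=list)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names")
        for s in self.sets:
            if not s.genes:
                raise ValueError(f"gene set {s.name!r} is empty")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def as_dict(self) -> dict[str, list[str]]:
        return {s.name: list(s.genes) for s in self.sets}


def read_gene_sets_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member1 TAB member2 ...

    Duplicate members within a line are dropped (first occurrence kept);
    duplicate set names raise.
    """
    sets: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            members = list(dict.fromkeys(f for f in fields[2:] if f))
            sets.append(GeneSet(name=fields[0], description=fields[1], genes=members))
    return GeneSetCollection(sets=sets)


def write_gene_sets_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


#: semantic column types understood by read_table
_RANGE_CHECKS = {
    "unit_interval": lambda v: _check_unit_interval(v.to_numpy(dtype=float), v.name),
    "nonneg_int": lambda v: _check_nonneg_int(v, v.name),
    "float": lambda v: v.astype(float),
    "str": lambda v: v.astype(str),
}


def _check_unit_interval(arr, name) -> None:
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"column {name!r} has values outside [0, 1]")


def _check_nonneg_int(series, name) -> None:
    vals = series.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals != np.round(vals)):
        raise ValueError(f"column {name!r} has negative or non-integer values")


def read_table(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a headered TSV and validate it against a column schema.

    ``schema`` maps required column names to a semantic type tag, one of
    ``str``, ``float``, ``nonneg_int``, ``unit_interval``.  Extra columns
    are kept untouched; rows stay in file order.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        for col, kind in schema.items():
            if kind not in _RANGE_CHECKS:
                raise ValueError(f"unknown schema type {kind!r}")
            if kind == "float":
                df[col] = df[col].astype(float)
            elif kind == "str":
                df[col] = df[col].astype(str)
            else:
                _RANGE_CHECKS[kind](df[col])
    return df


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a result table as TSV with a comment line recording parameters."""
    from . import __version__

    with open(path, "w", encoding="utf-8") as fh:
        items = " ".join(f"{k}={v}" for k, v in (params or {}).items())
        fh.write(f"# evmap {__version__} {items}\n".rstrip() + "\n")
        df.to_csv(fh, sep="\t", index=False)
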