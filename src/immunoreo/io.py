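"""Reading, writing and reshaping expression data.

Expression matrices are plain pandas DataFrames: rows indexed by gene
identifier, columns by sample identifier, values non-negative and on a
linear scale (microarray intensity, FPKM or counts).  Gene identifiers are
opaque strings; callers must use consistent identifiers across matrices,
marker lists and references.  All on-disk formats are TSV (optionally
gzip-compressed), with ``#``-prefixed header comment lines for metadata.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "validate_matrix",
    "collapse_probes",
    "pseudobulk",
    "read_probe_map",
    "read_cell_labels",
    "read_fraction_table",
    "write_fraction_table",
    "read_marker_catalog",
]


def validate_matrix(matrix: pd.DataFrame, *, drop_missing: bool = False) -> pd.DataFrame:
    """Validate (and optionally clean) an expression matrix.

    Enforces: unique gene ids, unique sample ids, non-negative finite
    values, non-empty matrix.  With ``drop_missing=True``, rows containing
    any missing value are dropped with a logged count (rank comparisons are
    undefined on missing data); otherwise missing values raise.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty expression matrix")
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup[:5]}")
    na_rows = matrix.isna().any(axis=1)
    if na_rows.any():
        if not drop_missing:
            raise ValueError(f"{int(na_rows.sum())} gene rows contain missing values")
        logger.warning("dropping %d gene rows with missing values", int(na_rows.sum()))
        matrix = matrix.loc[~na_rows]
        if matrix.shape[0] == 0:
            raise ValueError("all rows dropped: every gene had missing values")
    neg = matrix.lt(0)
    if neg.any().any():
        row = matrix.index[neg.any(axis=1)][0]
        col = matrix.columns[neg.loc[row]][0]
        raise ValueError(f"negative expression value at gene {row!r}, sample {col!r}")
    return matrix


def read_matrix(path, fmt: str = "tsv") -> pd.DataFrame:
    """Read a genes-by-samples expression matrix from TSV (optionally .gz).

    First column holds gene ids, the header row sample ids; lines starting
    with ``#`` are metadata comments.  Duplicate gene rows are collapsed by
    arithmetic mean (the same rule applied to probes sharing a gene); rows
    with missing values are dropped with a logged count.
    """
    if fmt != "tsv":
        raise ValueError(f"unknown matrix dialect: {fmt!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        n_before = df.shape[0]
        df = df.groupby(level=0, sort=False).mean()
        logger.info("collapsed %d duplicate gene rows by mean", n_before - df.shape[0])
    df = validate_matrix(df, drop_missing=True)
    logger.info("read matrix %s: %d genes x %d samples", path.name, *df.shape)
    return df


def write_matrix(matrix: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a matrix as TSV (gzip if the path ends in .gz), with optional
    ``# key: value`` header comments."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        matrix.to_csv(fh, sep="\t", index_label="gene_id")


def read_probe_map(path) -> pd.Series:
    """Read a two-column TSV (probe_id, gene_id); blank gene_id = unmapped."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    df.columns = ["probe_id", "gene_id"][: df.shape[1]]
    return df.set_index("probe_id")["gene_id"]


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probes-by-samples matrix to gene level.

    Probes mapping to no gene (missing from the map, or blank gene id) and
    probes whose id maps to multiple genes are discarded; probes sharing a
    gene are averaged (arithmetic mean) per sample.
    """
    probe_map = probe_map[probe_map.astype(str).str.len() > 0]
    # a probe id occurring more than once in the map is ambiguous -> discard
    ambiguous = probe_map.index[probe_map.index.duplicated(keep=False)]
    if len(ambiguous):
        logger.info("discarding %d ambiguous probes", ambiguous.nunique())
        probe_map = probe_map[~probe_map.index.isin(ambiguous)]
    keep = probe_matrix.index.intersection(probe_map.index)
    if len(keep) == 0:
        raise ValueError("no probes survived gene mapping")
    dropped = probe_matrix.shape[0] - len(keep)
    if dropped:
        logger.info("discarding %d unmapped probes", dropped)
    sub = probe_matrix.loc[keep]
    genes = probe_map.loc[keep].to_numpy()
    out = sub.groupby(genes, sort=True).mean()
    out.index = out.index.astype(str)
    return validate_matrix(out)


def pseudobulk(
    cell_matrix: pd.DataFrame, labels: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a barcodes-by-genes matrix into per-donor pseudo-bulk.

    ``labels`` has columns (barcode_id, cell_type, donor_id) covering every
    column of ``cell_matrix``.  Each donor's pseudo-bulk column is the sum
    of that donor's barcode columns; the returned fraction table records,
    per donor and cell type, (cells of that type) / (total cells of the
    donor).

    Returns ``(bulk_matrix, fraction_table)`` where the fraction table has
    columns (sample_id, cell_type, fraction).
    """
    labels = labels.set_index("barcode_id") if "barcode_id" in labels.columns else labels
    missing = [c for c in cell_matrix.columns if c not in labels.index]
    if missing:
        raise ValueError(f"{len(missing)} barcodes lack labels, e.g. {missing[:3]}")
    lab = labels.loc[list(cell_matrix.columns)]
    bulk = cell_matrix.T.groupby(lab["donor_id"].to_numpy()).sum().T
    bulk.columns = bulk.columns.astype(str)
    counts = lab.groupby(["donor_id", "cell_type"]).size()
    totals = lab.groupby("donor_id").size()
    rows = [
        {"sample_id": donor, "cell_type": ct, "fraction": n / totals[donor]}
        for (donor, ct), n in counts.items()
    ]
    fractions = pd.DataFrame(rows, columns=["sample_id", "cell_type", "fraction"])
    return validate_matrix(bulk), fractions


def read_cell_labels(path) -> pd.DataFrame:
    """Read a three-column TSV (barcode_id, cell_type, donor_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = ["barcode_id", "cell_type", "donor_id"]
    if list(df.columns[:3]) != expected:
        df.columns = expected[: df.shape[1]]
    return df


def read_fraction_table(path) -> pd.DataFrame:
    """Read a three-column TSV (sample_id, cell_type, fraction)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["sample_id"] = df["sample_id"].astype(str)
    bad = (df["fraction"] < 0) | (df["fraction"] > 1)
    if bad.any():
        raise ValueError("fractions must lie in [0, 1]")
    return df


def write_fraction_table(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "wt") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_marker_catalog(path) -> dict[str, list[str]]:
    """Read a two-column TSV (cell_type, gene_id) into cell_type -> gene list."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["cell_type", "gene_id"]:
        df.columns = ["cell_type", "gene_id"][: df.shape[1]]
    catalog = {ct: sorted(set(g["gene_id"])) for ct, g in df.groupby("cell_type")}
    if not catalog or any(len(v) == 0 for v in catalog.values()):
        raise ValueError("marker catalog must map each cell type to >= 1 gene")
    return catalog
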