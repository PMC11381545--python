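"""Table I/O plus the quantification and depth-normalization rules.

All tables are plain TSV: header row of sample ids, first column the row
id, UTF-8, no quoting.  Quantification follows the marker-gene convention
for metagenomic species (MGS): a species' abundance in a sample is the
mean count over *all* of its marker genes (zeros included), zeroed when
fewer than 10% of the markers are detected, then per-million scaled.
Depth normalization subsamples each sample's gene counts without
replacement to a fixed total and drops samples below that total.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AbundanceMatrix,
    GeneCountMatrix,
    PresenceMatrix,
    scale_per_million,
    validate_metadata,
)

MIN_MARKER_FRACTION = 0.10  # species zeroed when detected-marker fraction < 10%


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_metadata(md)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(metadata).to_csv(path, sep="\t", index_label="sample_id")


def _read_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric cells in {path}, columns: {non_numeric}")
    return df


def read_abundance_table(path: str | Path, metadata_path: str | Path) -> AbundanceMatrix:
    """Read a species × sample abundance TSV joined with its metadata.

    Samples present in the matrix but absent from the metadata are a hard
    error naming the offenders (the converse — metadata rows without a
    matrix column — is allowed and ignored).
    """
    values = _read_matrix(path, "species_id")
    metadata = read_metadata(metadata_path)
    return AbundanceMatrix(values, metadata)


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="species_id")


def read_presence_table(path: str | Path, metadata_path: str | Path) -> PresenceMatrix:
    values = _read_matrix(path, "species_id")
    return PresenceMatrix(values.astype(bool), read_metadata(metadata_path))


def write_presence_table(matrix: PresenceMatrix, path: str | Path) -> None:
    matrix.values.astype(int).to_csv(path, sep="\t", index_label="species_id")


def read_marker_map(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column (species_id, gene_id) TSV into an ordered map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"species_id", "gene_id"} <= set(df.columns):
        raise ValueError("marker map requires columns species_id and gene_id")
    return {s: sub["gene_id"].tolist() for s, sub in df.groupby("species_id", sort=True)}


def write_marker_map(marker_map: dict[str, list[str]], path: str | Path) -> None:
    rows = [(s, g) for s, genes in marker_map.items() for g in genes]
    pd.DataFrame(rows, columns=["species_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_gene_counts(path: str | Path, marker_map_path: str | Path) -> GeneCountMatrix:
    counts = _read_matrix(path, "gene_id")
    return GeneCountMatrix(counts, read_marker_map(marker_map_path))


def downsize_counts(
    gene_counts: GeneCountMatrix,
    target_reads: int,
    seed: int | None = None,
) -> tuple[GeneCountMatrix, list[str]]:
    """Subsample each sample's counts without replacement to ``target_reads``.

    Samples whose total is below the target cannot be downsized and are
    dropped; their ids are returned so callers can report the exclusions.
    A retained column sums exactly to ``target_reads`` and every output
    count is bounded by the input count (a true subsample).
    """
    if target_reads < 1:
        raise ValueError("target_reads must be >= 1")
    rng = np.random.default_rng(seed)
    totals = gene_counts.counts.sum(axis=0)
    dropped = totals.index[totals < target_reads].tolist()
    kept = [c for c in gene_counts.counts.columns if c not in set(dropped)]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below {target_reads} reads: {dropped}",
            stacklevel=2,
        )
    out = {}
    for col in kept:
        colors = gene_counts.counts[col].to_numpy()
        if colors.sum() == target_reads:
            out[col] = colors
        else:
            out[col] = rng.multivariate_hypergeometric(colors, target_reads, method="marginals")
    df = pd.DataFrame(out, index=gene_counts.counts.index, dtype=np.int64)
    return GeneCountMatrix(df, gene_counts.marker_map), dropped


def mgs_abundance(
    gene_counts: GeneCountMatrix,
    metadata: pd.DataFrame,
    min_marker_fraction: float = MIN_MARKER_FRACTION,
) -> AbundanceMatrix:
    """Quantify species from marker genes and per-million scale.

    For each species the abundance is the arithmetic mean over all its
    marker genes, detected or not.  If the fraction of markers with a
    nonzero count in a sample is strictly below ``min_marker_fraction``
    the species is called unobserved there and set to zero (a tie at
    exactly the threshold is retained).
    """
    if not gene_counts.marker_map:
        raise ValueError("gene count matrix has no marker map")
    counts = gene_counts.counts
    rows = {}
    for species, markers in gene_counts.marker_map.items():
        missing = [g for g in markers if g not in counts.index]
        if missing:
            raise ValueError(f"species {species!r}: marker genes absent from counts: {missing[:5]}")
        block = counts.loc[markers]
        mean = block.mean(axis=0)
        seen_fraction = (block > 0).mean(axis=0)
        mean[seen_fraction < min_marker_fraction] = 0.0
        rows[species] = mean
    values = pd.DataFrame(rows).T
    values.index.name = "species_id"
    return AbundanceMatrix(scale_per_million(values), metadata)
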