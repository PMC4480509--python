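"""Count-matrix container and plain-text readers/writers.

Counts travel as genes x samples tables, either TSV (gene identifiers in the
first column, a header row of sample identifiers) or MatrixMarket triplets
with sidecar row/column name files. Sample metadata is a TSV keyed by
``sample_id`` with a ``group`` column (cell type, or ``"dilution"``) and
optional quality-control columns (``input_pg``, ``unique_exonic_reads``,
``percent_unique``, ``percent_short_fragments``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .errors import ValidationError

__all__ = [
    "CountMatrix",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_sample_meta",
    "write_sample_meta",
]


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample counts plus per-sample metadata.

    Parameters
    ----------
    counts:
        Genes as rows (index = gene identifiers), samples as columns.
    sample_meta:
        Per-sample table indexed by sample identifier. Missing entries are
        created empty; extra rows for unknown samples are rejected.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        values = c.to_numpy()
        if values.size and (values < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.issubdtype(values.dtype, np.integer):
            if values.size and not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integers")
            self.counts = c.astype(np.int64)
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.counts.columns.copy())
        else:
            meta = self.sample_meta
            unknown = meta.index.difference(self.counts.columns)
            if len(unknown):
                raise ValidationError(
                    f"metadata rows for unknown samples: {list(unknown)[:5]}"
                )
            self.sample_meta = meta.reindex(self.counts.columns)

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> pd.Series:
        """Per-sample total read counts."""
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids) -> "CountMatrix":
        ids = list(sample_ids)
        return CountMatrix(self.counts[ids], self.sample_meta.loc[ids])

    def select_genes(self, gene_ids) -> "CountMatrix":
        ids = list(gene_ids)
        return CountMatrix(self.counts.loc[ids], self.sample_meta)


# ----------------------------------------------------------------------
# TSV
# ----------------------------------------------------------------------

def write_counts_tsv(matrix: CountMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path, meta: pd.DataFrame | None = None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ----------------------------------------------------------------------
# MatrixMarket triplet + name files
# ----------------------------------------------------------------------

def write_counts_mtx(matrix: CountMatrix, prefix) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rownames.txt`` / ``.colnames.txt``."""
    prefix = Path(prefix)
    scipy_io.mmwrite(str(prefix.with_suffix(".mtx")),
                     sparse.coo_matrix(matrix.counts.to_numpy()))
    prefix.with_suffix(".rownames.txt").write_text(
        "\n".join(map(str, matrix.gene_ids)) + "\n")
    prefix.with_suffix(".colnames.txt").write_text(
        "\n".join(map(str, matrix.sample_ids)) + "\n")


def read_counts_mtx(prefix, meta: pd.DataFrame | None = None) -> CountMatrix:
    prefix = Path(prefix)
    mat = scipy_io.mmread(str(prefix.with_suffix(".mtx")))
    genes = prefix.with_suffix(".rownames.txt").read_text().splitlines()
    samples = prefix.with_suffix(".colnames.txt").read_text().splitlines()
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    counts = pd.DataFrame(dense, index=genes, columns=samples)
    return CountMatrix(counts, meta)
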