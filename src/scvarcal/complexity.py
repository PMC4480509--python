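"""Transcriptome-complexity summaries and genomic-region read partitioning.
Expressed genes carry at least one read in a sample; private genes carry a
read in exactly one sample of the dataset. The half-reads statistic is the
smallest number of top-expressed genes whose counts reach half a sample's
total. Region partitioning labels every base of each chromosome as exonic,
intronic, flanking (within 5 kb of a transcribed unit, up to the nearest
exonic region) or intergenic, with precedence exonic > intronic > flanking >
intergenic, and assigns reads by intersection-nonempty semantics.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import CountMatrix
from .normalize import NormalizedMatrix

__all__ = [
    "expressed_and_private_genes",
    "genes_covering_half_reads",
    "size_corrected_expressed",
    "RegionAnnotation",
    "build_region_annotation",
    "assign_read_regions",
]

REGION_LABELS = ("exonic", "intronic", "flanking", "intergenic")
_EXONIC, _INTRONIC, _FLANKING, _INTERGENIC = range(4)


def expressed_and_private_genes(matrix: CountMatrix
                                ) -> tuple[pd.Series, pd.Series]:
    """Per-sample expressed-gene and private-gene counts.

    A gene is expressed in a sample if it has at least one read there, and
    private to that sample if no other sample detects it."""
    detected = matrix.counts.to_numpy() >= 1
    expressed = pd.Series(detected.sum(axis=0), index=matrix.sample_ids,
                          name="expressed")
    single = detected.sum(axis=1) == 1
    private = pd.Series((detected & single[:, None]).sum(axis=0),
                        index=matrix.sample_ids, name="private")
    return expressed, private


def genes_covering_half_reads(matrix: CountMatrix, sample) -> int:
    """Smallest k such that the k largest gene counts reach >=50 % of the
    sample total; ties resolved by descending count then gene id."""
    counts = matrix.counts[sample]
    total = int(counts.sum())
    if total == 0:
        raise ValidationError(f"sample {sample!r} has zero total reads")
    order = np.lexsort((np.asarray(counts.index, dtype=object),
                        -counts.to_numpy()))
    cumulative = np.cumsum(counts.to_numpy()[order])
    return int(np.searchsorted(cumulative, 0.5 * total) + 1)


def size_corrected_expressed(
    norm: NormalizedMatrix,
    large_cell_samples,
    factor: float = 8.0,
) -> pd.Series:
    """Expressed-gene counts with a cell-size detection correction.

    For samples of large cell types the detection threshold is ``factor``
    times the smallest non-zero relative frequency observed in that sample
    (genes below it are ignored), compensating for the larger RNA pool of a
    big cell; other samples report their plain expressed-gene count.
    """
    if factor < 1:
        raise ConfigurationError("factor must be >= 1")
    large = set(large_cell_samples)
    out = {}
    for sample in norm.sample_ids:
        rf = norm.relative_frequencies[sample].to_numpy()
        nonzero = rf[rf > 0]
        if sample in large:
            if nonzero.size == 0:
                raise ValidationError(f"sample {sample!r} has no non-zero gene")
            threshold = factor * nonzero.min()
            out[sample] = int((rf >= threshold).sum())
        else:
            out[sample] = int(nonzero.size)
    return pd.Series(out, name="corrected_expressed")


# ----------------------------------------------------------------------
# Region annotation
# ----------------------------------------------------------------------

@dataclass
class RegionAnnotation:
    """Per-chromosome base-resolution region labels (a partition).

    Backed by per-base label arrays (synthetic chromosomes are small);
    ``intervals`` exposes the compressed disjoint labelled intervals,
    0-based half-open."""

    labels: dict[str, np.ndarray]

    @property
    def intervals(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.labels):
            arr = self.labels[chrom]
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(arr)]])
            for s, e in zip(starts, ends):
                rows.append({"chrom": chrom, "start": int(s), "end": int(e),
                             "label": REGION_LABELS[arr[s]]})
        return pd.DataFrame(rows)

    def label_fractions(self, chrom) -> pd.Series:
        arr = self.labels[chrom]
        counts = np.bincount(arr, minlength=4)
        return pd.Series(counts / len(arr), index=REGION_LABELS)


def build_region_annotation(
    gene_models: pd.DataFrame,
    chrom_sizes: dict[str, int],
    flank_bp: int = 5000,
) -> RegionAnnotation:
    """Partition chromosomes into exonic/intronic/flanking/intergenic.

    ``gene_models`` needs columns chrom, start, end, gene_id, strand and
    feature ('exon' rows; 'transcript' rows optional, otherwise each
    gene's span is the extent of its exons). Any exon from any source makes
    a base exonic; bases inside a transcribed unit but not exonic are
    intronic; bases within ``flank_bp`` of a transcribed unit, walking
    outward until the nearest exonic base, are flanking; the rest is
    intergenic.
    """
    required = {"chrom", "start", "end", "gene_id", "strand", "feature"}
    missing = required - set(gene_models.columns)
    if missing:
        raise ValidationError(f"gene models missing columns: {sorted(missing)}")
    gm = gene_models
    if ((gm["start"] >= gm["end"]) | (gm["start"] < 0)).any():
        raise ValidationError("malformed gene-model interval (start >= end "
                              "or negative coordinate)")
    labels = {c: np.full(int(n), _INTERGENIC, dtype=np.uint8)
              for c, n in chrom_sizes.items()}

    exonic = {c: np.zeros(int(n), dtype=bool) for c, n in chrom_sizes.items()}
    for _, row in gm[gm["feature"] == "exon"].iterrows():
        if row["chrom"] not in exonic:
            raise ValidationError(f"unknown chromosome {row['chrom']!r}")
        if row["end"] > chrom_sizes[row["chrom"]]:
            raise ValidationError("exon extends beyond chromosome end")
        exonic[row["chrom"]][int(row["start"]):int(row["end"])] = True

    transcripts = gm[gm["feature"] == "transcript"]
    if transcripts.empty:
        transcripts = (gm[gm["feature"] == "exon"]
                       .groupby(["chrom", "gene_id"])
                       .agg(start=("start", "min"), end=("end", "max"))
                       .reset_index())
    transcribed = {c: np.zeros(int(n), dtype=bool)
                   for c, n in chrom_sizes.items()}
    for _, row in transcripts.iterrows():
        transcribed[row["chrom"]][int(row["start"]):int(row["end"])] = True

    flanking = {c: np.zeros(int(n), dtype=bool)
                for c, n in chrom_sizes.items()}
    for _, row in transcripts.iterrows():
        chrom = row["chrom"]
        n = chrom_sizes[chrom]
        ex = exonic[chrom]
        # upstream flank: walk left from the transcript start
        s = int(row["start"])
        for offset in range(1, flank_bp + 1):
            pos = s - offset
            if pos < 0 or ex[pos]:
                break
            flanking[chrom][pos] = True
        # downstream flank: walk right from the transcript end
        e = int(row["end"])
        for offset in range(flank_bp):
            pos = e + offset
            if pos >= n or ex[pos]:
                break
            flanking[chrom][pos] = True

    for chrom in chrom_sizes:
        arr = labels[chrom]
        arr[flanking[chrom]] = _FLANKING
        arr[transcribed[chrom] & ~exonic[chrom]] = _INTRONIC
        arr[exonic[chrom]] = _EXONIC
    return RegionAnnotation(labels)


def assign_read_regions(
    reads: pd.DataFrame,
    annotation: RegionAnnotation,
) -> pd.DataFrame:
    """Per-sample fractions of reads over the four region labels.

    ``reads`` needs columns chrom, start, end, sample. Intersection-
    nonempty with precedence: a read overlapping any exonic base is exonic,
    else intronic if it touches intronic sequence, and so on.
    """
    required = {"chrom", "start", "end", "sample"}
    if required - set(reads.columns):
        raise ValidationError(f"reads need columns {sorted(required)}")
    assigned = []
    for _, row in reads.iterrows():
        arr = annotation.labels[row["chrom"]]
        s = max(0, int(row["start"]))
        e = min(len(arr), int(row["end"]))
        if e <= s:
            raise ValidationError("read interval empty or outside chromosome")
        assigned.append(int(arr[s:e].min()))  # precedence = smallest code
    frame = pd.DataFrame({"sample": reads["sample"].to_numpy(),
                          "label": [REGION_LABELS[a] for a in assigned]})
    out = (frame.groupby("sample")["label"]
           .value_counts(normalize=True)
           .unstack(fill_value=0.0)
           .reindex(columns=list(REGION_LABELS), fill_value=0.0))
    return out
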