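"""Sample QC, median-of-ratios normalization, PCA projection, saturation curves.

Size factors follow the median-of-ratios scheme: a pseudo-reference sample is
the per-gene geometric mean across samples of the genes detected in every
sample ("ubiquitously expressed"); each sample's size factor is the median,
over those reference genes, of the ratio of its count to the pseudo-reference.
Normalized counts are raw counts divided by the sample's size factor; relative
frequencies are raw counts divided by the sample's total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError, ValidationError
from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "QCReport",
    "qc_filter_samples",
    "compute_size_factors",
    "pca_projection",
    "saturation_curve",
]


@dataclass
class NormalizedMatrix:
    """Size factors, normalized counts and relative frequencies for one dataset."""

    size_factors: pd.Series
    normalized: pd.DataFrame
    relative_frequencies: pd.DataFrame
    sample_meta: pd.DataFrame
    counts: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.normalized.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.normalized.columns

    @property
    def n_samples(self) -> int:
        return self.normalized.shape[1]

    def select_samples(self, sample_ids) -> "NormalizedMatrix":
        ids = list(sample_ids)
        return NormalizedMatrix(
            self.size_factors[ids],
            self.normalized[ids],
            self.relative_frequencies[ids],
            self.sample_meta.loc[ids],
            self.counts[ids],
        )


def compute_size_factors(matrix: CountMatrix) -> NormalizedMatrix:
    """Median-of-ratios size factors and derived matrices.

    The reference gene set is all genes with a non-zero count in every sample
    (equivalently, non-zero geometric mean). The pseudo-reference geometric
    mean is computed in log space; the median is taken on the ratio scale
    (for an even reference set the two middle ratios average arithmetically).

    Raises
    ------
    NormalizationError
        If no gene is detected in every sample.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    ubiquitous = (counts > 0).all(axis=1)
    if not ubiquitous.any():
        raise NormalizationError(
            "no ubiquitously expressed gene: every gene has a zero in some "
            "sample, so the median-of-ratios pseudo-reference is undefined; "
            "filter samples or merge shallow libraries first"
        )
    log_ref = np.log(counts[ubiquitous]).mean(axis=1)  # pseudo-reference (log)
    ratios = counts[ubiquitous] / np.exp(log_ref)[:, None]
    factors = np.median(ratios, axis=0)
    size_factors = pd.Series(factors, index=matrix.sample_ids, name="size_factor")
    normalized = matrix.counts / size_factors
    totals = matrix.totals.astype(float)
    relfreq = matrix.counts / totals
    return NormalizedMatrix(size_factors, normalized, relfreq,
                            matrix.sample_meta.copy(), matrix.counts.copy())


# ----------------------------------------------------------------------
# Sample QC
# ----------------------------------------------------------------------

TRAIT_NAMES = ("percent_unique", "genes_gt10", "percent_short_fragments")


@dataclass
class QCReport:
    """Per-sample QC outcome: depth gate, per-trait pass/fail (NaN = trait
    unavailable) and the final keep decision."""

    table: pd.DataFrame

    @property
    def kept(self) -> list:
        return list(self.table.index[self.table["kept"]])


def qc_filter_samples(
    matrix: CountMatrix,
    min_exonic_reads: float = 5e6,
    traits_required: int = 2,
    min_percent_unique: float = 50.0,
    min_genes_gt10: int = 1500,
    max_percent_short: float = 80.0,
) -> tuple[list, QCReport]:
    """Apply the sample-inclusion rules.

    A sample is kept iff its unique exonic read total exceeds
    ``min_exonic_reads`` (taken from the ``unique_exonic_reads`` metadata
    column when present, otherwise the column sum) AND it passes enough of
    the three library traits: >=50 % uniquely mapping reads, >=1500 genes
    covered by more than ten reads, <80 % short fragments. A trait whose
    statistic is missing from the metadata is unavailable; the requirement is
    lowered by one per unavailable trait (samples lacking the short-fragment
    statistic need only one of the two remaining criteria when
    ``traits_required`` is 2).
    """
    meta = matrix.sample_meta
    rows = []
    genes_gt10 = (matrix.counts > 10).sum(axis=0)
    for sample in matrix.sample_ids:
        if "unique_exonic_reads" in meta.columns and pd.notna(
                meta.at[sample, "unique_exonic_reads"]):
            exonic = float(meta.at[sample, "unique_exonic_reads"])
        else:
            exonic = float(matrix.counts[sample].sum())
        depth_ok = exonic > min_exonic_reads

        def _meta(col):
            if col in meta.columns and pd.notna(meta.at[sample, col]):
                return float(meta.at[sample, col])
            return np.nan

        pct_unique = _meta("percent_unique")
        pct_short = _meta("percent_short_fragments")
        traits = {
            "percent_unique": (np.nan if np.isnan(pct_unique)
                               else float(pct_unique >= min_percent_unique)),
            "genes_gt10": float(genes_gt10[sample] >= min_genes_gt10),
            "percent_short_fragments": (np.nan if np.isnan(pct_short)
                                        else float(pct_short < max_percent_short)),
        }
        available = [v for v in traits.values() if not np.isnan(v)]
        n_missing = len(traits) - len(available)
        required = max(0, traits_required - n_missing)
        n_passed = int(sum(available))
        kept = depth_ok and n_passed >= required
        rows.append({"sample_id": sample, "unique_exonic_reads": exonic,
                     "depth_ok": depth_ok, **traits,
                     "traits_passed": n_passed, "traits_required": required,
                     "kept": kept})
    table = pd.DataFrame(rows).set_index("sample_id")
    kept = list(table.index[table["kept"]])
    if not kept:
        warnings.warn("no samples passed QC", stacklevel=2)
    return kept, QCReport(table)


# ----------------------------------------------------------------------
# PCA projection
# ----------------------------------------------------------------------

def pca_projection(
    norm: NormalizedMatrix,
    n_components: int = 3,
    center: bool = True,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples on principal axes of arcsine-transformed frequencies.

    The decomposition input is arcsin(sqrt(relative frequency)) per
    gene/sample, after excluding genes with zero counts in every sample.
    Genes are centered by default (scaling off), matching the usual PCA
    convention for variance-stabilised proportions.

    Returns
    -------
    coords:
        samples x components DataFrame (columns ``PC1``..).
    percent_sd:
        Percentage of total standard deviation (singular value share)
        explained by each returned axis.
    """
    rf = norm.relative_frequencies
    expressed = (rf.to_numpy() > 0).any(axis=1)
    y = np.arcsin(np.sqrt(rf.to_numpy()[expressed]))  # genes x samples
    x = y.T  # samples x genes
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"n_components reduced from {n_components} to rank {rank}",
            stacklevel=2)
        n_components = rank
    coords = u[:, :n_components] * s[:n_components]
    percent_sd = 100.0 * s[:n_components] / s.sum()
    frame = pd.DataFrame(coords, index=norm.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, percent_sd


# ----------------------------------------------------------------------
# Saturation curves
# ----------------------------------------------------------------------

def saturation_curve(
    matrix: CountMatrix,
    sample,
    depths,
    n_draws: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Detected-gene counts under random read subsampling.

    Reads are subsampled without replacement (multivariate hypergeometric
    over genes); a gene is detected if it retains at least one read.
    Returns a table with ``depth``, ``mean_detected`` and ``sd_detected``.
    """
    counts = matrix.counts[sample].to_numpy(dtype=np.int64)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        depth = int(depth)
        if depth > total:
            raise ValidationError(
                f"requested depth {depth} exceeds sample total {total}")
        if depth == 0:
            detected = np.zeros(n_draws)
        elif depth == total:
            detected = np.full(n_draws, float((counts > 0).sum()))
        else:
            draws = rng.multivariate_hypergeometric(
                counts, depth, size=n_draws, method="marginals")
            detected = (draws > 0).sum(axis=1).astype(float)
        rows.append({"depth": depth,
                     "mean_detected": detected.mean(),
                     "sd_detected": detected.std(ddof=0)})
    return pd.DataFrame(rows)
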