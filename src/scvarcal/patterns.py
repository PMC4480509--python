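"""Extreme-variability and consistency patterns: outlier-sum statistic,
Shapiro-Wilk consistency, divergent genes and the RNA half-life association.

The outlier-sum statistic standardises a gene's per-cell values by the
median and the median absolute deviation (unscaled MAD; when the MAD is
zero the smallest non-zero value observed across the transcriptome is used
instead, so genes whose variation is a single extreme cell are not lost),
then sums the standardized values beyond the upper Tukey fence
q75(z) + IQR(z). Genes classified as variable rank in the top 400 by this
statistic within a cell type and have an outlier sum of at least 100;
consistently expressed genes rank in the top 400 by the Shapiro-Wilk W
statistic with probability of normality above 0.005. A divergent gene is
variable in at least one cell type and consistent in at least one other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .normalize import NormalizedMatrix
from .reliability import ReliabilityThreshold

__all__ = [
    "outlier_sum",
    "classify_patterns",
    "PatternTable",
    "half_life_association",
]


def outlier_sum(
    values,
    transcriptome_min: float,
    two_sided: bool = False,
    mad_consistency_factor: float = 1.0,
) -> float:
    """Outlier-sum statistic of one gene's per-cell expression values.

    ``transcriptome_min`` is the smallest non-zero value observed across
    the whole transcriptome (the fallback scale when the MAD is zero).
    Outliers are standardized values strictly above q75(z) + IQR(z); with
    ``two_sided`` the mirrored lower fence contributes |z| as well. Returns
    0 when no value exceeds the fence.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ConfigurationError("outlier sum needs at least 4 values")
    if transcriptome_min <= 0:
        raise ConfigurationError("transcriptome_min must be positive")
    med = np.median(v)
    mad = np.median(np.abs(v - med)) * mad_consistency_factor
    scale = mad if mad > 0 else transcriptome_min
    z = (v - med) / scale
    q25, q75 = np.percentile(z, [25, 75])
    iqr = q75 - q25
    upper = z[z > q75 + iqr]
    total = float(upper.sum())
    if two_sided:
        lower = z[z < q25 - iqr]
        total += float(np.abs(lower).sum())
    return total


@dataclass
class PatternTable:
    """Long table of per-(gene, cell type) statistics and flags, plus the
    per-gene divergent flag (variable somewhere, consistent elsewhere)."""

    table: pd.DataFrame  # gene_id, cell_type, os, sw_w, sw_p, variable, consistent
    divergent: pd.Series  # indexed by gene_id, bool

    @property
    def divergent_genes(self) -> list:
        return list(self.divergent.index[self.divergent])


def _shapiro(values: np.ndarray) -> tuple[float, float]:
    if np.ptp(values) == 0:
        return -np.inf, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def classify_patterns(
    cells_by_type: dict[str, NormalizedMatrix],
    threshold: float | ReliabilityThreshold,
    top_n: int = 400,
    os_min: float = 100.0,
    sw_p_min: float = 0.005,
    value_scale: str = "normalized",
) -> PatternTable:
    """Flag variable / consistent genes per cell type and divergent genes.

    Values are normalized read counts by default (``value_scale`` may be
    ``"relfreq"``). Genes below the reliability threshold (mean relative
    frequency) within a cell type are skipped for that type. A gene flagged
    variable is never simultaneously flagged consistent within the same
    type (an outlier-dominated gene is not normal by construction).
    """
    thr = threshold.selected if isinstance(threshold, ReliabilityThreshold) \
        else float(threshold)
    if value_scale not in ("normalized", "relfreq"):
        raise ConfigurationError("value_scale must be 'normalized' or 'relfreq'")
    rows = []
    for cell_type, norm in cells_by_type.items():
        if norm.n_samples < 4:
            raise ConfigurationError(
                f"cell type {cell_type!r} has fewer than 4 cells")
        data = (norm.normalized if value_scale == "normalized"
                else norm.relative_frequencies)
        arr = data.to_numpy()
        nonzero = arr[arr > 0]
        if nonzero.size == 0:
            continue
        tmin = float(nonzero.min())
        keep = norm.relative_frequencies.mean(axis=1) >= thr
        genes = data.index[keep]
        if top_n > len(genes):
            warnings.warn(f"top_n={top_n} exceeds {len(genes)} thresholded "
                          f"genes in {cell_type!r}; using all", stacklevel=2)
        sub = data.loc[genes].to_numpy()
        os_vals = np.array([outlier_sum(row, tmin) for row in sub])
        sw = [_shapiro(row) for row in sub]
        sw_w = np.array([s[0] for s in sw])
        sw_p = np.array([s[1] for s in sw])
        gene_arr = np.asarray(genes, dtype=object)
        os_rank = np.empty(len(genes), dtype=int)
        os_rank[np.lexsort((gene_arr, -os_vals))] = np.arange(1, len(genes) + 1)
        sw_rank = np.empty(len(genes), dtype=int)
        sw_rank[np.lexsort((gene_arr, -sw_w))] = np.arange(1, len(genes) + 1)
        variable = (os_rank <= top_n) & (os_vals >= os_min)
        consistent = (sw_rank <= top_n) & (sw_p > sw_p_min) & ~variable
        rows.append(pd.DataFrame({
            "gene_id": gene_arr, "cell_type": cell_type,
            "os": os_vals, "sw_w": sw_w, "sw_p": sw_p,
            "variable": variable, "consistent": consistent,
        }))
    table = pd.concat(rows, ignore_index=True)
    by_gene = table.groupby("gene_id")[["variable", "consistent"]].any()
    divergent_ids = set()
    for gene, grp in table.groupby("gene_id"):
        var_types = set(grp.loc[grp["variable"], "cell_type"])
        con_types = set(grp.loc[grp["consistent"], "cell_type"])
        if var_types and (con_types - var_types):
            divergent_ids.add(gene)
    divergent = pd.Series(
        [g in divergent_ids for g in by_gene.index],
        index=by_gene.index, name="divergent")
    return PatternTable(table, divergent)


def half_life_association(
    patterns: PatternTable,
    half_lives: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """Contingency of (variable vs consistent) x (fast vs slow decay).

    Genes are ranked by half-life (ties broken by gene id for determinism);
    the lower third is fast-decaying, the upper third slow-decaying, the
    middle is dropped. Genes that are both variable (in some type) and
    consistent (in another) are ambiguous and excluded. Returns the 2x2
    table, the chi-square statistic (no continuity correction, matching the
    textbook formula) and its p-value; if a margin is empty the test is
    skipped with a warning (statistic and p NaN).
    """
    hl = half_lives.rename(columns=dict(zip(half_lives.columns,
                                            ["gene_id", "half_life"])))
    flags = patterns.table.groupby("gene_id")[["variable", "consistent"]].any()
    flags = flags[flags["variable"] != flags["consistent"]]  # exactly one
    merged = flags.join(hl.set_index("gene_id"), how="inner")
    if len(merged) < 100:
        raise ValidationError(
            f"half-life table covers only {len(merged)} flagged genes (<100)")
    merged = merged.sort_values(["half_life", "gene_id"],
                                kind="mergesort")  # stable tie-break
    n = len(merged)
    third = n // 3
    fast = merged.iloc[:third]
    slow = merged.iloc[n - third:]
    table = pd.DataFrame(
        [[int(fast["variable"].sum()), int(slow["variable"].sum())],
         [int(fast["consistent"].sum()), int(slow["consistent"].sum())]],
        index=["variable", "consistent"], columns=["fast", "slow"])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty contingency margin; chi-square test skipped",
                      stacklevel=2)
        return table, float("nan"), float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return table, float(chi2), float(p)
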