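"""Expression-matched F-statistic and downstream variability analyses.

For gene *i* with mean relative frequency *x_i* within one cell type,

    F_i = V_total(i) / V_exp(x_i)

where V_total is the unbiased sample variance of relative frequencies across
that type's cells and V_exp is the technical-variance control curve evaluated
at matched expression level. Both numerator and denominator use the same
(n-1) estimator, so the ratio behaves like a studentized F: values near 1
indicate purely technical variation, values >> 1 biological variability.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .normalize import NormalizedMatrix
from .reliability import ControlCurve, ReliabilityThreshold

__all__ = [
    "f_statistic",
    "top_variable_genes",
    "category_ancova",
    "AncovaResult",
    "cross_species_partial_correlation",
    "PartialCorrelationResult",
    "within_between_variance",
]


def f_statistic(
    cells: NormalizedMatrix,
    curve: ControlCurve,
    threshold: float | ReliabilityThreshold,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-gene variability table for one cell type (or control group).

    Genes with mean relative frequency below the reliability threshold are
    excluded. Columns: ``mean_relfreq``, ``mean_norm`` (mean normalized
    depth), ``v_total``, ``v_exp``, ``f_stat``, ``rank`` (1 = most variable)
    and ``top_flag`` (top ``top_fraction`` by F).

    Applying this to the dilution replicates themselves is the negative
    control: their F distribution should centre on 1.
    """
    if cells.n_samples < 3:
        raise ConfigurationError("need at least 3 cells to estimate variance")
    thr = threshold.selected if isinstance(threshold, ReliabilityThreshold) \
        else float(threshold)
    rf = cells.relative_frequencies
    mean_rf = rf.mean(axis=1)
    keep = mean_rf >= thr
    rf = rf.loc[keep]
    mean_rf = mean_rf[keep]
    v_total = rf.var(axis=1, ddof=1)
    v_exp = pd.Series(curve.lookup(mean_rf.to_numpy()), index=rf.index)
    positive = v_exp > 0
    if (~positive).any():
        warnings.warn(f"{int((~positive).sum())} genes dropped: control "
                      "variance is zero at their expression level",
                      stacklevel=2)
    table = pd.DataFrame({
        "mean_relfreq": mean_rf[positive],
        "mean_norm": cells.normalized.loc[rf.index[positive]].mean(axis=1),
        "v_total": v_total[positive],
        "v_exp": v_exp[positive],
    })
    table["f_stat"] = table["v_total"] / table["v_exp"]
    order = np.lexsort((np.asarray(table.index, dtype=object),
                        -table["mean_relfreq"].to_numpy(),
                        -table["f_stat"].to_numpy()))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    k = math.ceil(top_fraction * len(table))
    table["top_flag"] = table["rank"] <= k
    return table


def top_variable_genes(table: pd.DataFrame, fraction: float = 0.05) -> list:
    """The ceil(fraction * n) genes with largest F.

    Ties at the cut are broken by larger mean expression, then gene id.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must lie in (0, 1]")
    if table.empty:
        raise ConfigurationError("variability table is empty")
    k = math.ceil(fraction * len(table))
    order = np.lexsort((np.asarray(table.index, dtype=object),
                        -table["mean_relfreq"].to_numpy(),
                        -table["f_stat"].to_numpy()))
    return list(np.asarray(table.index, dtype=object)[order][:k])


# ----------------------------------------------------------------------
# Functional-category ANCOVA
# ----------------------------------------------------------------------

@dataclass
class AncovaResult:
    """Adjusted category means of log10 F and all pairwise contrasts.

    ``pairs`` holds one row per category pair: the adjusted-mean difference
    at the average covariate value, simultaneous 95 % confidence bounds and
    a family-wise-corrected p-value (max-|t| over the joint t distribution
    of the contrast set)."""

    adjusted_means: pd.Series
    pairs: pd.DataFrame
    model: object
    n_multi_category_excluded: int
    n_dropped_small: int


def category_ancova(
    tables: dict[str, pd.DataFrame],
    categories: pd.DataFrame,
    min_genes: int = 2,
    conf_level: float = 0.95,
    n_mc: int = 20_000,
) -> AncovaResult:
    """Two-factor ANCOVA of log10 F on category + cell type + expression.

    ``tables`` maps cell type to a variability table (from
    :func:`f_statistic`); ``categories`` is a two-column table (``gene_id``,
    ``category``). Genes annotated to multiple categories are excluded
    (ambiguous factor level); categories with fewer than ``min_genes`` genes
    are dropped with a warning. The covariate is log10 mean normalized read
    depth; adjusted means are evaluated at the grand mean covariate,
    averaging cell-type effects with equal weight. Pairwise contrasts carry
    simultaneous confidence intervals and family-wise p-values from the
    joint t distribution of the contrast estimates (Tukey-style max-|t|,
    seeded Monte Carlo, deterministic).
    """
    cats = categories.rename(columns=dict(zip(categories.columns,
                                              ["gene_id", "category"])))
    counts_per_gene = cats.groupby("gene_id")["category"].nunique()
    multi = set(counts_per_gene.index[counts_per_gene > 1])
    cat_map = (cats[~cats["gene_id"].isin(multi)]
               .set_index("gene_id")["category"])

    frames = []
    for cell_type, table in tables.items():
        sub = table[(table["f_stat"] > 0) & (table["mean_norm"] > 0)]
        matched = sub.index.intersection(cat_map.index)
        if len(matched) == 0:
            continue
        frames.append(pd.DataFrame({
            "log_f": np.log10(sub.loc[matched, "f_stat"]),
            "log_depth": np.log10(sub.loc[matched, "mean_norm"]),
            "category": cat_map.loc[matched].to_numpy(),
            "cell_type": cell_type,
        }))
    data = pd.concat(frames, ignore_index=True)
    sizes = data["category"].value_counts()
    small = sizes.index[sizes < min_genes]
    n_dropped = len(small)
    if n_dropped:
        warnings.warn(f"dropping categories with <{min_genes} genes: "
                      f"{list(small)}", stacklevel=2)
        data = data[~data["category"].isin(small)]
    if data["category"].nunique() < 2:
        raise ConfigurationError("need at least two categories after filtering")

    res = smf.ols("log_f ~ C(category) + C(cell_type) + log_depth",
                  data=data).fit()
    design_info = res.model.data.design_info
    cat_levels = sorted(data["category"].unique())
    type_levels = sorted(data["cell_type"].unique())
    mean_cov = data["log_depth"].mean()

    def adjusted_row(category):
        new = pd.DataFrame({"category": category, "cell_type": type_levels,
                            "log_depth": mean_cov})
        (mat,) = build_design_matrices([design_info], new)
        return np.asarray(mat).mean(axis=0)

    rows = {c: adjusted_row(c) for c in cat_levels}
    beta = res.params.to_numpy()
    cov = res.cov_params().to_numpy()
    adjusted = pd.Series({c: float(rows[c] @ beta) for c in cat_levels},
                         name="adjusted_mean_log10_f")

    pairs = list(itertools.combinations(cat_levels, 2))
    C = np.vstack([rows[a] - rows[b] for a, b in pairs])
    est = C @ beta
    V = C @ cov @ C.T
    se = np.sqrt(np.diag(V))
    t_obs = est / se
    df = int(res.df_resid)

    # max-|t| reference distribution over the joint t of the contrasts
    R = V / np.outer(se, se)
    eigval, eigvec = np.linalg.eigh(R)
    factor = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None)))
    rng = np.random.default_rng(20150609)  # fixed: deterministic inference
    z = rng.standard_normal((n_mc, len(pairs))) @ factor.T
    w = rng.chisquare(df, size=n_mc) / df
    t_samples = z / np.sqrt(w)[:, None]
    max_abs = np.abs(t_samples).max(axis=1)
    q = float(np.quantile(max_abs, conf_level))
    p_fwer = (np.sum(max_abs[:, None] >= np.abs(t_obs)[None, :], axis=0) + 1
              ) / (n_mc + 1)

    pair_table = pd.DataFrame({
        "category_1": [a for a, _ in pairs],
        "category_2": [b for _, b in pairs],
        "difference": est,
        "ci_low": est - q * se,
        "ci_high": est + q * se,
        "p_fwer": p_fwer,
    })
    return AncovaResult(adjusted, pair_table, res, len(multi), n_dropped)


# ----------------------------------------------------------------------
# Cross-species partial correlation
# ----------------------------------------------------------------------

@dataclass
class PartialCorrelationResult:
    rho: float
    p_value: float
    n_genes: int
    coef_a: np.ndarray  # (b0, b1, b2) for species A regression
    coef_b: np.ndarray
    residuals_a: np.ndarray
    residuals_b: np.ndarray


def cross_species_partial_correlation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    homologues: pd.DataFrame,
    min_genes: int = 30,
) -> PartialCorrelationResult:
    """Partial correlation of log10 F between species given both species'
    expression levels.

    ``homologues`` is a two-column one-to-one map (species A id, species B
    id); ambiguous (duplicated) entries raise. Genes must pass the
    reliability threshold in both species, i.e. appear in both variability
    tables. Per species, log10 F is regressed on an intercept and the log10
    mean expression of BOTH species; rho is the Pearson correlation of the
    two residual vectors, with a two-sided t-test on n - 4 degrees of
    freedom.
    """
    hom = homologues.rename(columns=dict(zip(homologues.columns,
                                             ["species_a", "species_b"])))
    if hom["species_a"].duplicated().any() or hom["species_b"].duplicated().any():
        raise ValidationError(
            "homologue map is not one-to-one; pre-filter to unambiguous pairs")
    hom = hom[hom["species_a"].isin(table_a.index)
              & hom["species_b"].isin(table_b.index)]
    finite = ((table_a.loc[hom["species_a"], "f_stat"].to_numpy() > 0)
              & (table_a.loc[hom["species_a"], "mean_norm"].to_numpy() > 0)
              & (table_b.loc[hom["species_b"], "f_stat"].to_numpy() > 0)
              & (table_b.loc[hom["species_b"], "mean_norm"].to_numpy() > 0))
    hom = hom[finite]
    n = len(hom)
    if n < min_genes:
        raise ConfigurationError(
            f"only {n} shared homologues above threshold (< {min_genes})")
    fa = np.log10(table_a.loc[hom["species_a"], "f_stat"].to_numpy())
    fb = np.log10(table_b.loc[hom["species_b"], "f_stat"].to_numpy())
    xa = np.log10(table_a.loc[hom["species_a"], "mean_norm"].to_numpy())
    xb = np.log10(table_b.loc[hom["species_b"], "mean_norm"].to_numpy())
    X = np.column_stack([np.ones(n), xa, xb])
    coef_a, *_ = np.linalg.lstsq(X, fa, rcond=None)
    coef_b, *_ = np.linalg.lstsq(X, fb, rcond=None)
    ra = fa - X @ coef_a
    rb = fb - X @ coef_b
    rho = float(np.corrcoef(ra, rb)[0, 1])
    df = n - 4  # two covariates per species beyond the pair itself
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1 - rho ** 2))
        p = 2 * stats.t.sf(abs(t), df)
    return PartialCorrelationResult(rho, float(p), n, coef_a, coef_b, ra, rb)


# ----------------------------------------------------------------------
# Within / between cell-type variance
# ----------------------------------------------------------------------

def within_between_variance(
    by_type: dict[str, NormalizedMatrix],
) -> tuple[pd.Series, pd.DataFrame]:
    """Mean per-gene variance within each type and across pooled type pairs.

    Values are computed on arcsine-transformed relative frequencies
    (arcsin sqrt rf). Within-type variance is the mean over genes of the
    per-gene sample variance across that type's cells; the between-pair
    value pools all cells of both types and takes the same mean per-gene
    variance (the pooled decomposition is stated here because it is not
    uniquely determined by "variance between each pair"). Types with a
    single cell report NaN within-variance.
    """
    if len(by_type) < 2:
        raise ConfigurationError("need at least two cell types")
    transformed = {}
    for name, norm in by_type.items():
        transformed[name] = np.arcsin(
            np.sqrt(norm.relative_frequencies.to_numpy()))
    within = {}
    for name, arr in transformed.items():
        within[name] = (np.nan if arr.shape[1] < 2
                        else float(arr.var(axis=1, ddof=1).mean()))
    rows = []
    for a, b in itertools.combinations(sorted(by_type), 2):
        pooled = np.hstack([transformed[a], transformed[b]])
        rows.append({"type_1": a, "type_2": b,
                     "between_variance": float(
                         pooled.var(axis=1, ddof=1).mean())})
    return pd.Series(within, name="within_variance"), pd.DataFrame(rows)
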