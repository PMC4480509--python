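"""Universal / common gene identification, Jaccard overlap testing and a
generic enrichment engine over user-supplied annotation tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .io import CountMatrix

__all__ = [
    "universal_genes",
    "common_genes_by_type",
    "jaccard_overlap_test",
    "GeneListComparison",
    "filter_one_to_one_homologues",
    "enrichment_test",
]


def universal_genes(matrix: CountMatrix) -> list:
    """Genes with at least one read in every sample."""
    mask = (matrix.counts.to_numpy() >= 1).all(axis=1)
    return list(matrix.gene_ids[mask])


def common_genes_by_type(
    matrix: CountMatrix,
    cell_type: str,
    universal,
    top_n: int = 400,
    use_normalized: bool = False,
    normalized: pd.DataFrame | None = None,
) -> list:
    """Top genes by minimum count across one cell type's cells.

    Universal genes are excluded; genes are ranked by descending minimum
    (raw) count in any cell of the type, ties broken by descending mean
    count then gene id. Raw counts are the default scale (set
    ``use_normalized`` and pass the normalized matrix to switch).
    """
    cells = matrix.sample_meta.index[matrix.sample_meta["group"] == cell_type]
    if len(cells) < 2:
        raise ConfigurationError(
            f"cell type {cell_type!r} has fewer than 2 cells")
    if use_normalized:
        if normalized is None:
            raise ConfigurationError(
                "use_normalized requires the normalized matrix")
        data = normalized[cells]
    else:
        data = matrix.counts[cells]
    candidates = data.drop(index=[g for g in universal if g in data.index])
    min_count = candidates.min(axis=1).to_numpy(dtype=float)
    mean_count = candidates.mean(axis=1).to_numpy(dtype=float)
    gene_arr = np.asarray(candidates.index, dtype=object)
    order = np.lexsort((gene_arr, -mean_count, -min_count))
    if top_n > len(gene_arr):
        warnings.warn(f"only {len(gene_arr)} candidate genes for top_n="
                      f"{top_n}; returning all", stacklevel=2)
    return list(gene_arr[order][:top_n])


# ----------------------------------------------------------------------
# Jaccard overlap with permutation p-value
# ----------------------------------------------------------------------

@dataclass
class GeneListComparison:
    jaccard: float
    p_value: float
    p_is_upper_bound: bool  # True => zero exceedances, report p < 1/n_perm
    n_permutations: int
    n_a: int
    n_b: int
    seed: int | None


def jaccard_overlap_test(
    list_a,
    list_b,
    universe_a,
    universe_b,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> GeneListComparison:
    """Jaccard index of two gene lists with a matched-size permutation test.

    Identifiers must already live in a common (homologue-mapped) namespace.
    The p-value is the fraction of ``n_perm`` random same-size draws from
    each universe whose Jaccard index is greater than or equal to the
    observed one; zero exceedances are reported as p = 1/n_perm with
    ``p_is_upper_bound`` set (read: p < 1/n_perm).
    """
    A, B = set(list_a), set(list_b)
    UA, UB = list(dict.fromkeys(universe_a)), list(dict.fromkeys(universe_b))
    if not A <= set(UA) or not B <= set(UB):
        raise ValidationError("lists must be subsets of their universes")
    union = A | B
    if not union:
        raise ValidationError("both lists empty: Jaccard index undefined")
    j_obs = len(A & B) / len(union)
    rng = np.random.default_rng(seed)
    ua = np.asarray(UA, dtype=object)
    ub = np.asarray(UB, dtype=object)
    na, nb = len(A), len(B)
    exceed = 0
    for _ in range(n_perm):
        sa = set(ua[rng.choice(len(ua), na, replace=False)])
        sb = set(ub[rng.choice(len(ub), nb, replace=False)])
        inter = len(sa & sb)
        jp = inter / (na + nb - inter)
        if jp >= j_obs:
            exceed += 1
    if exceed == 0:
        return GeneListComparison(j_obs, 1.0 / n_perm, True, n_perm, na, nb, seed)
    return GeneListComparison(j_obs, exceed / n_perm, False, n_perm, na, nb, seed)


def filter_one_to_one_homologues(homologues: pd.DataFrame
                                 ) -> tuple[pd.DataFrame, int]:
    """Drop homologue rows whose gene appears more than once in either
    species; returns the filtered map and the number of rows removed."""
    hom = homologues.rename(columns=dict(zip(homologues.columns,
                                             ["species_a", "species_b"])))
    ok = (~hom["species_a"].duplicated(keep=False)
          & ~hom["species_b"].duplicated(keep=False))
    return hom[ok].reset_index(drop=True), int((~ok).sum())


# ----------------------------------------------------------------------
# Generic enrichment engine
# ----------------------------------------------------------------------

def enrichment_test(
    genes,
    background,
    annotations: pd.DataFrame,
    method: str = "hypergeometric",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term enrichment of a gene set against a background.

    ``annotations`` is a two-column (gene, term) table. For each term with
    at least one annotated background gene, the 2x2 table of (in query /
    not) x (annotated / not) is tested by the upper-tail hypergeometric
    test or a chi-square test, with Bonferroni correction across tested
    terms. The enrichment ratio is the fraction of query genes carrying the
    term relative to the same fraction among the remaining background genes.
    """
    if method not in ("hypergeometric", "chi_square"):
        raise ConfigurationError(f"unknown method {method!r}")
    query = set(genes)
    bg = set(background)
    if not query <= bg:
        raise ValidationError("query genes must be a subset of the background")
    ann = annotations.rename(columns=dict(zip(annotations.columns,
                                              ["gene_id", "term"])))
    ann = ann[ann["gene_id"].isin(bg)]
    N, n = len(bg), len(query)
    rows = []
    for term, grp in ann.groupby("term"):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        rest_with = K - k
        rest_total = N - n
        frac_query = k / n if n else 0.0
        if rest_total == 0 or rest_with == 0:
            ratio = np.inf if frac_query > 0 else np.nan
        else:
            ratio = frac_query / (rest_with / rest_total)
        if method == "hypergeometric":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = np.array([[k, n - k], [rest_with, rest_total - rest_with]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1])
        rows.append({"term": term, "query_with_term": k,
                     "background_with_term": K, "enrichment_ratio": ratio,
                     "p_raw": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_bonferroni"] = np.minimum(out["p_raw"] * len(out), 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out.sort_values("p_raw", kind="mergesort").reset_index(drop=True)
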