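"""F-statistic calibration, variable-gene selection, category ANCOVA,
cross-species partial correlation and within/between variances."""

import math

import numpy as np
import pandas as pd
import pytest

import scvarcal as sv
from scvarcal.errors import ConfigurationError, ValidationError
from conftest import make_norm


def _norm_from_rows(rows, prefix="c", genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i:04d}" for i in range(rows.shape[0])]
    cols = [f"{prefix}{j}" for j in range(rows.shape[1])]
    return make_norm(pd.DataFrame(rows, index=genes, columns=cols))


def _gaussian_pair(rng, n_genes, n_dil, n_cells, cell_var_factor=1.0):
    """Dilution + cell matrices sharing per-gene means; the cell variance is
    a known multiple of the dilution (technical) variance."""
    base = np.linspace(1e-4, 1e-2, n_genes)
    sigma = 0.05 * base
    dil = base[:, None] + sigma[:, None] * rng.standard_normal((n_genes, n_dil))
    cells = base[:, None] + (math.sqrt(cell_var_factor) * sigma[:, None]
                             * rng.standard_normal((n_genes, n_cells)))
    return _norm_from_rows(dil, "d"), _norm_from_rows(cells, "c")


# ----------------------------------------------------------------------
# F-statistic
# ----------------------------------------------------------------------

def test_constant_gene_has_zero_f(rng):
    dil, cells = _gaussian_pair(rng, 60, 12, 8)
    cells.relative_frequencies.iloc[30] = 5e-3  # identical in every cell
    curve = sv.build_control_curve(dil, window_genes=15)
    table = sv.f_statistic(cells, curve, threshold=0.0)
    assert table.loc["g0030", "f_stat"] == 0.0
    assert (table.f_stat >= 0).all()


def test_f_statistic_null_median_near_one(rng):
    """Cells drawn from the same technical model as the dilution controls
    give a median F near 1 (compact version of the full calibration)."""
    dil, cells = _gaussian_pair(rng, 1500, 12, 20)
    curve = sv.build_control_curve(dil, window_genes=301)
    table = sv.f_statistic(cells, curve, threshold=0.0)
    assert 0.85 < table.f_stat.median() < 1.15
    assert (table.f_stat > 10).mean() < 0.01


def test_planted_variance_additivity_recovers_f_of_ten(rng):
    """Biological variance 9x the technical variance added on top of it
    gives mean F near 10 (the small positive bias is the median-variance
    denominator)."""
    dil, cells = _gaussian_pair(rng, 2000, 12, 20, cell_var_factor=10.0)
    curve = sv.build_control_curve(dil, window_genes=301)
    table = sv.f_statistic(cells, curve, threshold=0.0)
    assert 9.0 < table.f_stat.mean() < 11.7


def test_f_statistic_requires_three_cells(rng):
    dil, cells = _gaussian_pair(rng, 30, 12, 2)
    curve = sv.build_control_curve(dil, window_genes=7)
    with pytest.raises(ConfigurationError):
        sv.f_statistic(cells, curve, threshold=0.0)


def test_threshold_excludes_low_expression_genes(rng):
    dil, cells = _gaussian_pair(rng, 100, 12, 10)
    curve = sv.build_control_curve(dil, window_genes=21)
    table = sv.f_statistic(cells, curve, threshold=5e-3)
    assert (table.mean_relfreq >= 5e-3).all()
    assert len(table) < 100


# ----------------------------------------------------------------------
# Top variable genes
# ----------------------------------------------------------------------

def _toy_table(f_values):
    n = len(f_values)
    return pd.DataFrame({
        "mean_relfreq": np.linspace(1e-4, 1e-3, n),
        "mean_norm": np.linspace(10, 100, n),
        "f_stat": f_values,
    }, index=[f"g{i:03d}" for i in range(n)])


def test_top_variable_genes_order_statistics(rng):
    table = _toy_table(rng.random(100) * 5)
    top5 = sv.top_variable_genes(table, 0.05)
    assert len(top5) == 5
    worst_kept = table.loc[top5, "f_stat"].min()
    assert (table.drop(index=top5).f_stat <= worst_kept).all()
    assert set(sv.top_variable_genes(table, 1.0)) == set(table.index)


def test_top_variable_genes_nested_fractions(rng):
    table = _toy_table(rng.random(200))
    assert set(sv.top_variable_genes(table, 0.05)) <= \
        set(sv.top_variable_genes(table, 0.10))


def test_top_variable_genes_rejects_bad_fraction(rng):
    table = _toy_table(rng.random(10))
    for frac in (0.0, -0.1, 1.5):
        with pytest.raises(ConfigurationError):
            sv.top_variable_genes(table, frac)


def test_top_variable_gene_recovery_of_planted_inflation():
    """Planted 10x-variance genes are recovered by the top-5% rule
    (compact version of the full recovery run)."""
    recalls = []
    for seed in range(5):
        spec = sv.SyntheticSpec(n_genes=2000, seed=600 + seed,
                                planted_mode="inflation",
                                cell_type_sizes={"a": 20})
        dil = sv.compute_size_factors(sv.simulate_dilution_counts(spec, 10.0))
        curve = sv.build_control_curve(dil, window_genes=301)
        cells, truth = sv.simulate_cell_type_counts(spec)
        nc = sv.compute_size_factors(cells)
        thr = sv.evaluate_reliability_criteria(dil, nc, curve,
                                               with_breakpoint=False)
        table = sv.f_statistic(nc, curve, thr.select((1, 3)))
        top = set(sv.top_variable_genes(table, 0.05))
        planted = set(truth[truth.hypervariable].gene_id) & set(table.index)
        recalls.append(len(top & planted) / len(planted))
    assert np.mean(recalls) >= 0.85


# ----------------------------------------------------------------------
# Category ANCOVA
# ----------------------------------------------------------------------

def _ancova_data(rng, n=2000, effect=0.3, cov_slope=0.5):
    """One cell type, two categories, planted category effect on log10 F."""
    genes = [f"g{i:04d}" for i in range(n)]
    cov = rng.uniform(1, 3, n)  # log10 mean depth
    cat = np.where(np.arange(n) % 2 == 0, "catA", "catB")
    log_f = (0.2 + cov_slope * cov + np.where(cat == "catA", effect, 0.0)
             + 0.3 * rng.standard_normal(n))
    table = pd.DataFrame({
        "mean_relfreq": 10.0 ** (cov - 6),
        "mean_norm": 10.0 ** cov,
        "f_stat": 10.0 ** log_f,
    }, index=genes)
    categories = pd.DataFrame({"gene_id": genes, "category": cat})
    return table, categories


def test_ancova_recovers_planted_category_effect(rng):
    table, categories = _ancova_data(rng, effect=0.3)
    res = sv.category_ancova({"ct1": table}, categories)
    row = res.pairs.iloc[0]
    diff = row.difference if row.category_1 == "catA" else -row.difference
    assert abs(diff - 0.3) < 0.05
    assert row.ci_low < row.difference < row.ci_high
    assert res.pairs.p_fwer.iloc[0] < 0.01


def test_ancova_null_covariate_slope_ci_covers_zero(rng):
    table, categories = _ancova_data(rng, effect=0.0, cov_slope=0.0)
    res = sv.category_ancova({"ct1": table}, categories)
    lo, hi = res.model.conf_int().loc["log_depth"]
    assert lo < 0 < hi


def test_ancova_interval_coverage_under_identical_distributions():
    """Equal category distributions: the simultaneous 95 % interval for the
    difference covers zero at close to nominal rate."""
    cover = 0
    n_sim = 300
    rng = np.random.default_rng(123)
    for _ in range(n_sim):
        table, categories = _ancova_data(rng, n=400, effect=0.0)
        res = sv.category_ancova({"ct1": table}, categories)
        row = res.pairs.iloc[0]
        cover += row.ci_low <= 0 <= row.ci_high
    assert cover / n_sim >= 0.92


def test_ancova_differences_match_normal_equations(rng):
    table, categories = _ancova_data(rng, n=200)
    res = sv.category_ancova({"ct1": table}, categories)
    # brute-force OLS on the explicit design matrix
    cat = categories.set_index("gene_id").loc[table.index, "category"]
    X = np.column_stack([np.ones(len(table)),
                         (cat == "catB").to_numpy(float),
                         np.log10(table.mean_norm)])
    y = np.log10(table.f_stat.to_numpy())
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    expected_diff = -beta[1]  # catA - catB
    row = res.pairs.iloc[0]
    diff = row.difference if row.category_1 == "catA" else -row.difference
    assert abs(diff - expected_diff) < 1e-8


def test_ancova_excludes_multi_category_genes(rng):
    table, categories = _ancova_data(rng, n=100)
    extra = pd.DataFrame({"gene_id": ["g0000"], "category": ["catB"]})
    res = sv.category_ancova({"ct1": table},
                             pd.concat([categories, extra]))
    assert res.n_multi_category_excluded == 1


# ----------------------------------------------------------------------
# Cross-species partial correlation
# ----------------------------------------------------------------------

def _species_tables(f_a, f_b, x_a, x_b):
    genes_a = [f"m{i:04d}" for i in range(len(f_a))]
    genes_b = [f"r{i:04d}" for i in range(len(f_b))]
    ta = pd.DataFrame({"f_stat": f_a, "mean_norm": x_a}, index=genes_a)
    tb = pd.DataFrame({"f_stat": f_b, "mean_norm": x_b}, index=genes_b)
    hom = pd.DataFrame({"species_a": genes_a, "species_b": genes_b})
    return ta, tb, hom


def test_partial_correlation_perfect_conservation(rng):
    f = 10.0 ** rng.standard_normal(500)
    x = 10.0 ** rng.uniform(1, 3, 500)
    ta, tb, hom = _species_tables(f, f, x, x)
    res = sv.cross_species_partial_correlation(ta, tb, hom)
    assert res.rho == pytest.approx(1.0, abs=1e-9)
    assert res.p_value < 1e-10


def test_partial_correlation_removes_shared_expression_confound(rng):
    x = rng.uniform(1, 3, 5000)
    noise_a = 0.01 * rng.standard_normal(5000)
    noise_b = 0.01 * rng.standard_normal(5000)
    f_a = 10.0 ** (0.8 * x + noise_a)   # F driven by expression only
    f_b = 10.0 ** (0.8 * x + noise_b)
    ta, tb, hom = _species_tables(f_a, f_b, 10.0 ** x, 10.0 ** x)
    res = sv.cross_species_partial_correlation(ta, tb, hom)
    assert abs(res.rho) < 0.05


def test_partial_correlation_recovers_planted_rho():
    spec = sv.SyntheticSpec(n_genes=5000, seed=31,
                            planted_cross_species_rho=0.5)
    result = sv.simulate_two_species(spec, n_cells=(3, 3))
    ta, tb = sv.true_variability_tables(result)
    res = sv.cross_species_partial_correlation(ta, tb, result.homologues)
    assert abs(res.rho - 0.5) < 0.05
    assert res.p_value < 1e-10


def test_partial_correlation_invariant_to_log_scale_shift(rng):
    x = rng.uniform(1, 3, 800)
    f_a = 10.0 ** (0.3 * x + 0.2 * rng.standard_normal(800))
    f_b = 10.0 ** (0.3 * x + 0.2 * rng.standard_normal(800))
    ta, tb, hom = _species_tables(f_a, f_b, 10.0 ** x, 10.0 ** x)
    base = sv.cross_species_partial_correlation(ta, tb, hom)
    ta2 = ta.assign(mean_norm=ta.mean_norm * 100)  # +2 in log10
    tb2 = tb.assign(mean_norm=tb.mean_norm * 1000)
    shifted = sv.cross_species_partial_correlation(ta2, tb2, hom)
    assert shifted.rho == pytest.approx(base.rho, abs=1e-10)


def test_partial_correlation_rejects_ambiguous_homologues(rng):
    f = 10.0 ** rng.standard_normal(50)
    x = 10.0 ** rng.uniform(1, 3, 50)
    ta, tb, hom = _species_tables(f, f, x, x)
    bad = pd.concat([hom, hom.iloc[[0]]])
    with pytest.raises(ValidationError):
        sv.cross_species_partial_correlation(ta, tb, bad)


def test_partial_correlation_residuals_orthogonal_to_covariates(rng):
    x_a = rng.uniform(1, 3, 300)
    x_b = x_a + 0.1 * rng.standard_normal(300)
    f_a = 10.0 ** rng.standard_normal(300)
    f_b = 10.0 ** rng.standard_normal(300)
    ta, tb, hom = _species_tables(f_a, f_b, 10.0 ** x_a, 10.0 ** x_b)
    res = sv.cross_species_partial_correlation(ta, tb, hom)
    for r in (res.residuals_a, res.residuals_b):
        assert abs(np.dot(r, x_a)) < 1e-6 * np.linalg.norm(r) * np.linalg.norm(x_a)
        assert abs(np.dot(r, x_b)) < 1e-6 * np.linalg.norm(r) * np.linalg.norm(x_b)


# ----------------------------------------------------------------------
# Within / between variances
# ----------------------------------------------------------------------

def test_identical_populations_between_matches_within(rng):
    rows = rng.dirichlet(np.ones(50), size=8).T
    a = _norm_from_rows(rows[:, :4], "a")
    b = _norm_from_rows(rows[:, 4:], "b")
    within, between = sv.within_between_variance({"a": a, "b": b})
    pair = between.between_variance.iloc[0]
    assert pair == pytest.approx(within.mean(), rel=0.5)


def test_disjoint_types_between_far_exceeds_within(rng):
    a_rows = np.zeros((40, 4))
    b_rows = np.zeros((40, 4))
    a_rows[:20] = 1 / 20 + 1e-4 * rng.standard_normal((20, 4))
    b_rows[20:] = 1 / 20 + 1e-4 * rng.standard_normal((20, 4))
    a = _norm_from_rows(a_rows, "a")
    b = _norm_from_rows(b_rows, "b")
    within, between = sv.within_between_variance({"a": a, "b": b})
    assert between.between_variance.iloc[0] > 10 * within.max()


def test_within_between_hand_fixture():
    a = _norm_from_rows([[0.2, 0.4], [0.5, 0.3], [0.3, 0.3]], "a")
    b = _norm_from_rows([[0.6, 0.8], [0.2, 0.1], [0.2, 0.1]], "b")
    within, between = sv.within_between_variance({"a": a, "b": b})
    ta = np.arcsin(np.sqrt([[0.2, 0.4], [0.5, 0.3], [0.3, 0.3]]))
    tb = np.arcsin(np.sqrt([[0.6, 0.8], [0.2, 0.1], [0.2, 0.1]]))
    assert within["a"] == pytest.approx(ta.var(axis=1, ddof=1).mean())
    pooled = np.hstack([ta, tb])
    assert between.between_variance.iloc[0] == pytest.approx(
        pooled.var(axis=1, ddof=1).mean())


def test_single_cell_type_rejected(rng):
    a = _norm_from_rows(rng.random((10, 3)), "a")
    with pytest.raises(ConfigurationError):
        sv.within_between_variance({"a": a})


def test_one_cell_type_reports_missing_within(rng):
    a = _norm_from_rows(rng.random((10, 1)), "a")
    b = _norm_from_rows(rng.random((10, 3)), "b")
    within, _ = sv.within_between_variance({"a": a, "b": b})
    assert math.isnan(within["a"])
    assert math.isfinite(within["b"])
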