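"""Generator contracts: design echo, noise-free limits, closed-form variance,
noise monotonicity, determinism, planted structure and annotation planting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import scvarcal as sv
from scvarcal.errors import ConfigurationError, ValidationError


def test_dilution_design_echo():
    spec = sv.SyntheticSpec(n_genes=300, seed=1, target_depth=50_000)
    m = sv.simulate_dilution_counts(spec, 10.0)
    assert m.counts.shape == (300, 12)
    assert (m.totals == spec.target_depth).all()
    assert (m.sample_meta["input_pg"] == 10.0).all()
    assert (m.sample_meta["group"] == "dilution").all()


def test_unknown_input_pg_is_configuration_error():
    spec = sv.SyntheticSpec(n_genes=50, seed=1)
    with pytest.raises(ConfigurationError):
        sv.simulate_dilution_counts(spec, 25.0)


def test_noise_free_limit_reproduces_bulk_profile_exactly():
    spec = sv.SyntheticSpec(n_genes=400, seed=2, capture_efficiency=1.0,
                            amplification_noise_sd=0.0)
    bulk = sv.bulk_molecule_profile(spec)
    _, weights = sv.simulate_dilution_counts(spec, 10.0, return_weights=True)
    freq = weights / weights.sum(axis=0)
    expected = bulk / bulk.sum()
    for col in freq:
        np.testing.assert_array_equal(freq[col].to_numpy(), expected)


def test_dilution_variance_matches_compound_binomial_multinomial_oracle():
    """Monte-Carlo count variance vs the closed-form capture+sequencing
    variance (delta method on the multinomial frequency) for a gene at 10
    expected molecules."""
    n_genes, M, D, e = 200, 150_000, 200_000, 0.5
    bulk = np.full(n_genes, 0, dtype=np.int64)
    bulk[0] = 10
    bulk[1:] = (M - 10) // (n_genes - 1)
    bulk[1] += (M - 10) - int(bulk[1:].sum())  # make the total exact
    assert bulk.sum() == M
    spec = sv.SyntheticSpec(n_genes=n_genes, seed=3, capture_efficiency=e,
                            amplification_noise_sd=0.0, target_depth=D,
                            dilution_design=((10.0, 10_000),))
    m = sv.simulate_dilution_counts(spec, 10.0, bulk_molecules=bulk)
    counts = m.counts.iloc[0].to_numpy()
    mc_var = counts.var(ddof=1)

    g, t = bulk[0], M * e
    pi = g / M
    var_c = g * e * (1 - e)
    var_t = M * e * (1 - e)
    var_f = (var_c * (1 - 2 * pi) + pi ** 2 * var_t) / t ** 2
    oracle = D * pi * (1 - pi) + D * (D - 1) * var_f
    assert abs(mc_var - oracle) / oracle < 0.05


def test_technical_cv_decreases_with_input_amount_and_abundance():
    spec = sv.SyntheticSpec(
        n_genes=300, seed=4, target_depth=100_000,
        dilution_design=((10.0, 300), (50.0, 300), (100.0, 300)))
    bulk = sv.bulk_molecule_profile(spec)
    mid = (bulk > 20) & (bulk < 500)  # genes with nontrivial capture noise
    cvs = {}
    for pg in (10.0, 50.0, 100.0):
        m = sv.simulate_dilution_counts(spec, pg, bulk_molecules=bulk)
        arr = m.counts.to_numpy()[mid].astype(float)
        mean = arr.mean(axis=1)
        keep = mean > 0
        cvs[pg] = (arr.std(axis=1, ddof=1)[keep] / mean[keep]).mean()
    assert cvs[100.0] < cvs[50.0] < cvs[10.0]

    # CV also falls with gene abundance at fixed input amount
    m10 = sv.simulate_dilution_counts(spec, 10.0, bulk_molecules=bulk)
    arr = m10.counts.to_numpy().astype(float)
    mean = arr.mean(axis=1)
    cv = np.where(mean > 0, arr.std(axis=1, ddof=1) / np.maximum(mean, 1e-9),
                  np.nan)
    order = np.argsort(bulk)
    low = np.nanmean(cv[order][50:100])
    high = np.nanmean(cv[order][-50:])
    assert high < low


def test_seed_determinism_and_divergence():
    spec = sv.SyntheticSpec(n_genes=120, seed=9, target_depth=20_000)
    a = sv.simulate_dilution_counts(spec, 10.0)
    b = sv.simulate_dilution_counts(spec, 10.0)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    other = sv.SyntheticSpec(n_genes=120, seed=10, target_depth=20_000)
    c = sv.simulate_dilution_counts(other, 10.0)
    assert not a.counts.equals(c.counts)


def test_cell_type_truth_labels_shared_but_counts_differ():
    spec = sv.SyntheticSpec(n_genes=200, seed=5, target_depth=30_000,
                            cell_type_sizes={"a": 5, "b": 5})
    matrix, truth = sv.simulate_cell_type_counts(spec)
    la = truth[truth.cell_type == "a"].set_index("gene_id")["hypervariable"]
    lb = truth[truth.cell_type == "b"].set_index("gene_id")["hypervariable"]
    pd.testing.assert_series_equal(la, lb)
    a_cols = [c for c in matrix.sample_ids if c.startswith("a_")]
    b_cols = [c for c in matrix.sample_ids if c.startswith("b_")]
    assert not np.array_equal(matrix.counts[a_cols].to_numpy(),
                              matrix.counts[b_cols].to_numpy())


def test_no_planting_gives_pure_background_dispersion():
    spec = sv.SyntheticSpec(n_genes=150, seed=6, target_depth=20_000,
                            planted_hypervariable=(0.0, 16.0, 0.5),
                            cell_type_sizes={"a": 4})
    _, truth = sv.simulate_cell_type_counts(spec)
    assert not truth.hypervariable.any()
    assert truth.true_bio_cv2.nunique() == 1


def test_planted_fraction_above_one_rejected():
    with pytest.raises(ConfigurationError):
        sv.SyntheticSpec(planted_hypervariable=(1.5, 16.0, 0.5))


def test_mixture_planting_is_bimodal_across_cells():
    """On/off planted genes (fold 16, p=0.5) show a wide multiplicative gap
    between their two expression modes in nearly all simulated samples.

    Bimodality is scored at the maximal adjacent gap of the sorted counts:
    the two resulting groups must be non-empty and differ at least 4x in
    mean. The 16x mode separation shrinks by the within-mode spread
    (background dispersion plus capture and renormalisation noise) but the
    group means stay far apart, while a unimodal background gene splits
    into groups within ~1.5x of each other."""
    hits = trials = 0
    for seed in range(45):
        spec = sv.SyntheticSpec(n_genes=300, seed=100 + seed,
                                target_depth=200_000,
                                cell_type_sizes={"a": 20})
        matrix, truth = sv.simulate_cell_type_counts(spec)
        t = truth[truth.cell_type == "a"].set_index("gene_id")
        genes = t.index[t.hypervariable & (t.base_molecules > 100)]
        for g in genes:
            vals = np.sort(matrix.counts.loc[g].to_numpy() + 1.0)
            split = int(np.argmax(vals[1:] / vals[:-1])) + 1
            if vals[split:].mean() / vals[:split].mean() >= 4:
                hits += 1
            trials += 1
    assert trials >= 200
    assert hits / trials >= 0.95


def test_column_sums_match_target_depth():
    spec = sv.SyntheticSpec(n_genes=100, seed=7, target_depth=40_000,
                            cell_type_sizes={"a": 3})
    matrix, _ = sv.simulate_cell_type_counts(spec)
    assert (matrix.totals == spec.target_depth).all()


# ----------------------------------------------------------------------
# Two species
# ----------------------------------------------------------------------

@pytest.mark.parametrize("rho,bound", [(0.0, 0.05), (0.5, 0.03)])
def test_two_species_dispersion_correlation(rho, bound):
    spec = sv.SyntheticSpec(n_genes=5000, seed=8, planted_cross_species_rho=rho)
    res = sv.simulate_two_species(spec, n_cells=(3, 3))
    r = np.corrcoef(res.truth.dispersion_a, res.truth.dispersion_b)[0, 1]
    assert abs(r - rho) < bound


def test_two_species_rho_one_is_degenerate_identity():
    spec = sv.SyntheticSpec(n_genes=500, seed=8, planted_cross_species_rho=1.0)
    res = sv.simulate_two_species(spec, n_cells=(3, 3))
    np.testing.assert_allclose(res.truth.dispersion_a, res.truth.dispersion_b)


def test_two_species_rho_above_one_rejected():
    with pytest.raises(ConfigurationError):
        sv.SyntheticSpec(planted_cross_species_rho=1.2)


def test_two_species_homologue_map_is_one_to_one():
    spec = sv.SyntheticSpec(n_genes=200, seed=8)
    res = sv.simulate_two_species(spec, n_cells=(3, 3))
    assert res.homologues.species_a.is_unique
    assert res.homologues.species_b.is_unique
    assert len(res.homologues) == 200
    assert set(res.homologues.species_a) == set(res.counts_a.gene_ids)


# ----------------------------------------------------------------------
# Read starts
# ----------------------------------------------------------------------

def test_read_start_end_outside_span_is_validation_error():
    spec = sv.SyntheticSpec(seed=1)
    layout = sv.make_gene_layout(["g1"])
    with pytest.raises(ValidationError):
        sv.simulate_read_starts(spec, layout, {"g1": {"typeA": [99_999]}})


def test_read_start_dropout_gives_empty_tracks():
    spec = sv.SyntheticSpec(seed=1)
    layout = sv.make_gene_layout(["g1"])
    data = sv.simulate_read_starts(spec, layout, {"g1": {}},
                                   dropout_rate=1.0, n_cells_per_type=2)
    assert all(t.is_empty for t in data.tracks.values())


def test_read_start_planted_end_recovered_by_caller():
    spec = sv.SyntheticSpec(seed=2)
    layout = sv.make_gene_layout(["g1"])
    end = int(layout.annotated_end.iloc[0]) - 300
    data = sv.simulate_read_starts(spec, layout, {"g1": {"typeA": [end]}},
                                   cell_types=("typeA",), n_cells_per_type=4,
                                   end_excess=50)
    for cell in data.cells.cell_id:
        called = sv.call_track_ends(data.tracks[("g1", cell)],
                                    int(layout.annotated_end.iloc[0]))
        assert len(called) == 1
        assert abs(called[0] - end) <= 50


# ----------------------------------------------------------------------
# Annotations
# ----------------------------------------------------------------------

def test_annotation_tables_cover_every_gene():
    spec = sv.SyntheticSpec(n_genes=250, seed=3)
    hl, cat, ph = sv.simulate_annotations(spec)
    for table in (hl, cat, ph):
        assert len(table) == 250
        assert table.gene_id.is_unique
        assert not table.isna().any().any()


def _half_life_chi2_p(spec, or_planted):
    hl, _, _ = sv.simulate_annotations(spec, half_life_odds_ratio=or_planted)
    hv = sv.synthetic.hypervariable_gene_mask(spec)
    order = np.argsort(hl.half_life_h.to_numpy())
    n = len(order)
    third = n // 3
    fast = np.zeros(n, dtype=bool)
    fast[order[:third]] = True
    slow = np.zeros(n, dtype=bool)
    slow[order[-third:]] = True
    table = np.array([[np.sum(hv & fast), np.sum(hv & slow)],
                      [np.sum(~hv & fast), np.sum(~hv & slow)]])
    return stats.chi2_contingency(table, correction=False)[1]


def test_half_life_planting_type_one_error_calibrated():
    """With no planted association, the chi-square test rejects at the
    nominal rate."""
    rejections = 0
    n_sim = 400
    for seed in range(n_sim):
        spec = sv.SyntheticSpec(n_genes=600, seed=5000 + seed,
                                planted_hypervariable=(0.3, 16.0, 0.5))
        if _half_life_chi2_p(spec, 1.0) < 0.05:
            rejections += 1
    assert 0.02 <= rejections / n_sim <= 0.09


def test_half_life_planting_has_power_at_odds_ratio_eight():
    detected = 0
    n_sim = 100
    for seed in range(n_sim):
        spec = sv.SyntheticSpec(n_genes=600, seed=7000 + seed,
                                planted_hypervariable=(0.3, 16.0, 0.5))
        if _half_life_chi2_p(spec, 8.0) < 0.05:
            detected += 1
    assert detected / n_sim >= 0.90
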