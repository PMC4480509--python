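"""Synthetic single-cell RNA-seq data with the statistical structure the
analysis assumes.

The generative chain for every sequenced sample is

    molecules  ->  binomial capture  ->  log-normal amplification
               ->  multinomial sequencing to a fixed read depth

which reproduces the two qualitative facts the calibration relies on:
technical noise grows as gene expression and input RNA amount fall, and
genes below a few tens of molecules drop out. Dilution controls share one
fixed bulk molecule profile (10 pg of total RNA is modelled as a pool of
150,000 mRNA molecules; 50 and 100 pg scale linearly). Cell-type samples
add a biological layer: a per-type expression profile, small log-normal
background dispersion, and planted hypervariable genes, either two-state
on/off mixtures or calibrated variance inflation relative to the technical
noise floor. Ground truth (which genes were planted, their biological
dispersion) is emitted alongside every matrix so downstream tests never
have to re-derive it from realized data.

All randomness flows from a single integer seed through named,
deterministically derived streams: identical spec + seed reproduce every
output exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import CountMatrix
from .utr import ReadStartTrack

__all__ = [
    "SyntheticSpec",
    "bulk_molecule_profile",
    "simulate_dilution_counts",
    "simulate_cell_type_counts",
    "simulate_two_species",
    "TwoSpeciesResult",
    "true_variability_tables",
    "make_gene_layout",
    "simulate_read_starts",
    "ReadStartData",
    "simulate_annotations",
]

#: the five mouse cell types of the emulated study design
DEFAULT_CELL_TYPES: dict[str, int] = {
    "brown_adipocyte": 13,
    "cardiomyocyte": 19,
    "pyramidal_cortex": 19,
    "pyramidal_hippocampus": 18,
    "serotonergic": 22,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """All simulation parameters; identical spec + seed => identical output.

    Defaults emulate the study design: 91 cells over five cell types,
    dilution replicates of one bulk profile at 10 pg (12x), 50 pg (9x) and
    100 pg (9x), a 150,000-molecule pool per 10 pg, and a wide log-normal
    abundance distribution (about 30 molecules per gene on average at the
    default gene count).
    """

    n_genes: int = 5000
    cell_type_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    dilution_design: tuple[tuple[float, int], ...] = (
        (10.0, 12), (50.0, 9), (100.0, 9))
    mean_expression_model: tuple[float, float] = (math.log(30.0), 2.0)
    capture_efficiency: float = 0.3
    amplification_noise_sd: float = 0.25
    target_depth: int = 500_000
    molecules_per_10pg: int = 150_000
    background_dispersion_sd: float = 0.15
    planted_hypervariable: tuple[float, float, float] = (0.05, 16.0, 0.5)
    planted_mode: str = "mixture"          # or "inflation"
    variance_inflation: float = 10.0       # used by planted_mode="inflation"
    planted_cross_species_rho: float = 0.5
    cross_species_dispersion_sd: float = 0.3   # log10 scale
    seed: int = 0

    def __post_init__(self) -> None:
        frac, fold, on_p = self.planted_hypervariable
        if not 0 <= frac <= 1:
            raise ConfigurationError("planted fraction must lie in [0, 1]")
        if fold <= 1:
            raise ConfigurationError("planted fold-change must exceed 1")
        if not 0 <= on_p <= 1:
            raise ConfigurationError("on-probability must lie in [0, 1]")
        if not 0 < self.capture_efficiency <= 1:
            raise ConfigurationError("capture_efficiency must lie in (0, 1]")
        if self.amplification_noise_sd < 0:
            raise ConfigurationError("amplification_noise_sd must be >= 0")
        if self.target_depth <= 0:
            raise ConfigurationError("target_depth must be positive")
        if abs(self.planted_cross_species_rho) > 1:
            raise ConfigurationError("cross-species rho must lie in [-1, 1]")
        if self.planted_mode not in ("mixture", "inflation"):
            raise ConfigurationError("planted_mode must be 'mixture' or "
                                     "'inflation'")
        if self.variance_inflation <= 1:
            raise ConfigurationError("variance_inflation must exceed 1")

    def stream(self, name: str) -> np.random.Generator:
        """Named RNG stream derived deterministically from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(name.encode())]))

    @property
    def gene_ids(self) -> np.ndarray:
        width = max(4, len(str(self.n_genes)))
        return np.array([f"g{i:0{width}d}" for i in range(self.n_genes)],
                        dtype=object)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integerise non-negative weights so they sum exactly to ``total``."""
    scaled = weights / weights.sum() * total
    floor = np.floor(scaled).astype(np.int64)
    short = total - int(floor.sum())
    if short > 0:
        order = np.argsort(-(scaled - floor), kind="stable")
        floor[order[:short]] += 1
    return floor


def bulk_molecule_profile(spec: SyntheticSpec) -> np.ndarray:
    """The fixed bulk profile: integer molecules per gene in a 10 pg pool."""
    mu, sigma = spec.mean_expression_model
    rng = spec.stream("bulk-profile")
    abundance = rng.lognormal(mu, sigma, spec.n_genes)
    return _largest_remainder(abundance, spec.molecules_per_10pg)


def _sequence_sample(rng, molecules, spec,
                     return_weights=False):
    """Capture, amplify and sequence one sample's molecule vector."""
    captured = rng.binomial(molecules, spec.capture_efficiency)
    weights = captured.astype(float)
    if spec.amplification_noise_sd > 0:
        weights = weights * rng.lognormal(0.0, spec.amplification_noise_sd,
                                          len(weights))
    total = weights.sum()
    if total == 0:
        reads = np.zeros(len(weights), dtype=np.int64)
    else:
        reads = rng.multinomial(spec.target_depth, weights / total)
    return (reads, weights) if return_weights else reads


def simulate_dilution_counts(
    spec: SyntheticSpec,
    input_pg: float,
    bulk_molecules: np.ndarray | None = None,
    return_weights: bool = False,
    n_replicates: int | None = None,
    stream: str | None = None,
):
    """Replicate amplifications of one bulk profile diluted to ``input_pg``.

    Every replicate of every input amount shares the same bulk molecule
    profile, scaled linearly with the input mass; per-replicate noise is
    binomial capture, multiplicative log-normal amplification and a
    multinomial sequencing draw to the target depth. With
    ``return_weights`` the pre-sequencing weight matrix is returned too
    (in the noise-free limit its column frequencies equal the bulk profile
    exactly). ``n_replicates`` / ``stream`` override the design replicate
    count and the random stream, e.g. to draw an independent set of
    technical-only "cells" from the identical model.
    """
    design = dict(spec.dilution_design)
    if input_pg not in design:
        raise ConfigurationError(
            f"input_pg={input_pg} not in dilution design "
            f"{sorted(design)}")
    n_reps = design[input_pg] if n_replicates is None else int(n_replicates)
    m10 = bulk_molecules if bulk_molecules is not None \
        else bulk_molecule_profile(spec)
    if len(m10) != spec.n_genes:
        raise ConfigurationError("bulk profile length != n_genes")
    molecules = np.round(m10 * (input_pg / 10.0)).astype(np.int64)
    rng = spec.stream(stream if stream is not None
                      else f"dilution:{input_pg:g}")
    counts = np.empty((spec.n_genes, n_reps), dtype=np.int64)
    weight_cols = []
    for r in range(n_reps):
        reads, weights = _sequence_sample(rng, molecules, spec,
                                          return_weights=True)
        counts[:, r] = reads
        weight_cols.append(weights)
    sample_ids = [f"d{input_pg:g}pg_r{r + 1:02d}" for r in range(n_reps)]
    meta = pd.DataFrame({"group": "dilution", "input_pg": input_pg},
                        index=pd.Index(sample_ids, name="sample_id"))
    matrix = CountMatrix(pd.DataFrame(counts, index=spec.gene_ids,
                                      columns=sample_ids), meta)
    if return_weights:
        return matrix, pd.DataFrame(np.column_stack(weight_cols),
                                    index=spec.gene_ids, columns=sample_ids)
    return matrix


# ----------------------------------------------------------------------
# Cell types with planted biological structure
# ----------------------------------------------------------------------

def _technical_cv2(spec: SyntheticSpec, molecules: np.ndarray) -> np.ndarray:
    """Approximate technical CV^2 of one gene's read count given its
    molecule count: capture binomial + amplification log-normal +
    sequencing multinomial (Poisson-like at small relative frequency)."""
    m = np.maximum(molecules.astype(float), 1.0)
    e = spec.capture_efficiency
    expected_reads = np.maximum(
        spec.target_depth * m / m.sum(), 1e-9)
    return ((1 - e) / (m * e)
            + math.expm1(spec.amplification_noise_sd ** 2)
            + 1.0 / expected_reads)


def hypervariable_gene_mask(spec: SyntheticSpec) -> np.ndarray:
    """The planted hypervariable gene set (shared by all cell types)."""
    frac = spec.planted_hypervariable[0]
    n_planted = int(round(frac * spec.n_genes))
    rng = spec.stream("planting")
    mask = np.zeros(spec.n_genes, dtype=bool)
    mask[rng.choice(spec.n_genes, n_planted, replace=False)] = True
    return mask


def simulate_cell_type_counts(
    spec: SyntheticSpec,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Single-cell counts for every cell type, plus ground truth.

    Each cell type draws its own expression profile; per cell, background
    genes fluctuate around the type mean with small mean-preserving
    log-normal dispersion, while planted hypervariable genes follow either
    a two-state on/off mixture (off mean vs on mean x fold-change) or a
    calibrated log-normal whose biological variance is
    (variance_inflation - 1) times the technical variance at that gene's
    expression. Per-cell totals are renormalised to the cell molecule pool
    (fixed cellular mRNA content), then pushed through the technical chain.

    Returns the count matrix (samples = all cells, metadata ``group`` =
    cell type) and a long ground-truth table (gene_id, cell_type,
    hypervariable, true_bio_cv2).
    """
    if not spec.cell_type_sizes:
        raise ConfigurationError("cell_type_sizes must be non-empty")
    frac, fold, on_p = spec.planted_hypervariable
    hv = hypervariable_gene_mask(spec)
    s = spec.background_dispersion_sd
    cv2_background = math.expm1(s ** 2)
    pool = spec.molecules_per_10pg

    columns, sample_ids, groups, truth_rows = [], [], [], []
    for cell_type in spec.cell_type_sizes:
        n_cells = int(spec.cell_type_sizes[cell_type])
        profile_rng = spec.stream(f"celltype:{cell_type}:profile")
        mu, sigma = spec.mean_expression_model
        base = _largest_remainder(
            profile_rng.lognormal(mu, sigma, spec.n_genes), pool)
        cell_rng = spec.stream(f"celltype:{cell_type}:cells")

        if spec.planted_mode == "inflation":
            cv2_extra = (spec.variance_inflation - 1) * _technical_cv2(
                spec, base)
            sigma_extra = np.sqrt(np.log1p(cv2_extra))
        else:
            sigma_extra = None

        for c in range(n_cells):
            expr = base.astype(float)
            if s > 0:
                expr = expr * cell_rng.lognormal(-s ** 2 / 2, s, spec.n_genes)
            if hv.any():
                if spec.planted_mode == "mixture":
                    on = cell_rng.random(int(hv.sum())) < on_p
                    boost = np.where(on, fold, 1.0)
                    expr[hv] *= boost
                else:
                    se = sigma_extra[hv]
                    expr[hv] *= cell_rng.lognormal(-se ** 2 / 2, se)
            expr = expr / expr.sum() * pool  # fixed cellular mRNA content
            molecules = np.round(expr).astype(np.int64)
            columns.append(_sequence_sample(cell_rng, molecules, spec))
            sample_ids.append(f"{cell_type}_c{c + 1:02d}")
            groups.append(cell_type)

        # ground truth for this type
        if spec.planted_mode == "mixture":
            mean_boost = 1 + (fold - 1) * on_p
            cv2_mix = on_p * (1 - on_p) * (fold - 1) ** 2 / mean_boost ** 2
            cv2_hv = (1 + cv2_background) * (1 + cv2_mix) - 1
            cv2_hv = np.full(int(hv.sum()), cv2_hv)
        else:
            cv2_hv = ((1 + cv2_background)
                      * (1 + (spec.variance_inflation - 1)
                         * _technical_cv2(spec, base)[hv]) - 1)
        cv2 = np.full(spec.n_genes, cv2_background)
        cv2[hv] = cv2_hv
        truth_rows.append(pd.DataFrame({
            "gene_id": spec.gene_ids, "cell_type": cell_type,
            "hypervariable": hv, "true_bio_cv2": cv2,
            "base_molecules": base,
        }))

    counts = pd.DataFrame(np.column_stack(columns), index=spec.gene_ids,
                          columns=sample_ids)
    meta = pd.DataFrame({"group": groups},
                        index=pd.Index(sample_ids, name="sample_id"))
    return CountMatrix(counts, meta), pd.concat(truth_rows, ignore_index=True)


# ----------------------------------------------------------------------
# Two species with correlated excess dispersion
# ----------------------------------------------------------------------

@dataclass
class TwoSpeciesResult:
    counts_a: CountMatrix
    counts_b: CountMatrix
    homologues: pd.DataFrame  # columns species_a, species_b (one-to-one)
    truth: pd.DataFrame       # per-homologue means and planted dispersions


def simulate_two_species(
    spec: SyntheticSpec,
    n_cells: tuple[int, int] = (19, 8),
    expression_slope: float = 0.5,
) -> TwoSpeciesResult:
    """Two homologous single-cell datasets with correlated variability.

    Per-gene mean expression is shared between the species; per-gene excess
    dispersions (log10 scale) are drawn from a bivariate normal with
    correlation ``planted_cross_species_rho``, independently of the means.
    The truth table carries, per homologue pair, the shared log10 mean,
    both planted dispersions and the implied "true" F-statistics
    ``10**(expression_slope * log10(mean) + dispersion)`` — the quantities
    a perfect estimator would recover. Counts for each species are
    generated through the usual technical chain with per-gene biological
    log-normal noise scaled monotonically by the planted dispersion.
    """
    rho = spec.planted_cross_species_rho
    rng = spec.stream("two-species")
    mu, sigma = spec.mean_expression_model
    log_mean = rng.normal(mu, sigma, spec.n_genes)
    z1 = rng.standard_normal(spec.n_genes)
    z2 = rng.standard_normal(spec.n_genes)
    sd = spec.cross_species_dispersion_sd
    disp_a = sd * z1
    disp_b = sd * (rho * z1 + math.sqrt(max(0.0, 1 - rho ** 2)) * z2)

    pool = spec.molecules_per_10pg
    base = _largest_remainder(np.exp(log_mean), pool)
    ids_a = np.array([f"m_{i:05d}" for i in range(spec.n_genes)], dtype=object)
    ids_b = np.array([f"r_{i:05d}" for i in range(spec.n_genes)], dtype=object)

    def species_counts(prefix, disp, n, stream_name):
        srng = spec.stream(stream_name)
        sigma_g = spec.background_dispersion_sd * np.power(10.0, disp / 2)
        cols, names = [], []
        for c in range(n):
            expr = base * srng.lognormal(-sigma_g ** 2 / 2, sigma_g)
            expr = expr / expr.sum() * pool
            cols.append(_sequence_sample(srng, np.round(expr).astype(np.int64),
                                         spec))
            names.append(f"{prefix}_c{c + 1:02d}")
        return np.column_stack(cols), names

    arr_a, names_a = species_counts("speciesA", disp_a, n_cells[0],
                                    "two-species:A")
    arr_b, names_b = species_counts("speciesB", disp_b, n_cells[1],
                                    "two-species:B")
    meta_a = pd.DataFrame({"group": "speciesA"},
                          index=pd.Index(names_a, name="sample_id"))
    meta_b = pd.DataFrame({"group": "speciesB"},
                          index=pd.Index(names_b, name="sample_id"))
    counts_a = CountMatrix(pd.DataFrame(arr_a, index=ids_a, columns=names_a),
                           meta_a)
    counts_b = CountMatrix(pd.DataFrame(arr_b, index=ids_b, columns=names_b),
                           meta_b)
    homologues = pd.DataFrame({"species_a": ids_a, "species_b": ids_b})
    rel_mean = base / base.sum()
    log10_mean = np.log10(np.maximum(rel_mean, 1e-12))
    truth = pd.DataFrame({
        "species_a": ids_a, "species_b": ids_b,
        "log10_mean": log10_mean,
        "dispersion_a": disp_a, "dispersion_b": disp_b,
        "f_true_a": 10.0 ** (expression_slope * log10_mean + disp_a),
        "f_true_b": 10.0 ** (expression_slope * log10_mean + disp_b),
        "mean_molecules": base,
    })
    return TwoSpeciesResult(counts_a, counts_b, homologues, truth)


def true_variability_tables(result: TwoSpeciesResult
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth variability tables for the two species.

    Built from the planted quantities (true F and mean expression), in the
    column layout of :func:`scvarcal.variability.f_statistic`, for testing
    the cross-species machinery without estimation noise."""
    t = result.truth[result.truth["mean_molecules"] > 0]
    a = pd.DataFrame({"f_stat": t["f_true_a"].to_numpy(),
                      "mean_norm": t["mean_molecules"].to_numpy(dtype=float)},
                     index=pd.Index(t["species_a"], name="gene_id"))
    b = pd.DataFrame({"f_stat": t["f_true_b"].to_numpy(),
                      "mean_norm": t["mean_molecules"].to_numpy(dtype=float)},
                     index=pd.Index(t["species_b"], name="gene_id"))
    return a, b


# ----------------------------------------------------------------------
# Strand-resolved read-start tracks with planted 3' ends
# ----------------------------------------------------------------------

@dataclass
class ReadStartData:
    tracks: dict          # (gene_id, cell_id) -> ReadStartTrack
    genes: pd.DataFrame   # gene_id, chrom, start, end, strand, annotated_end
    cells: pd.DataFrame   # cell_id, cell_type


def make_gene_layout(
    gene_ids: Sequence[str],
    gene_length: int = 4000,
    spacing: int = 10_000,
    flank: int = 1000,
    chrom: str = "chrS",
) -> pd.DataFrame:
    """Lay genes out on one synthetic chromosome, annotated end ``flank``
    bases before the span end so the +-flank analysis window stays inside
    the span."""
    rows = []
    for i, gid in enumerate(gene_ids):
        start = i * spacing
        end = start + gene_length
        rows.append({"gene_id": gid, "chrom": chrom, "start": start,
                     "end": end, "strand": "+",
                     "annotated_end": end - flank})
    return pd.DataFrame(rows)


def simulate_read_starts(
    spec: SyntheticSpec,
    genes: pd.DataFrame,
    planted_ends: Mapping[str, Mapping[str, Sequence[int]]],
    cell_types: Sequence[str] = ("typeA", "typeB"),
    n_cells_per_type: int = 8,
    fragments_per_track: int = 300,
    end_excess: int = 30,
    orphan_rate: float = 0.05,
    dropout_rate: float = 0.0,
    per_cell_ends: Mapping[str, Mapping[str, Sequence[int]]] | None = None,
    stream: str = "read-starts",
) -> ReadStartData:
    """Per-cell strand-resolved read-start tracks with planted 3' ends.

    Random fragmentation places breakpoints uniformly over the transcript
    body; each breakpoint emits a matched sense + antisense read-start pair
    (with probability ``orphan_rate`` one mate is lost, the residual
    unpaired noise). Each planted end position receives ``end_excess``
    extra antisense starts concentrated immediately upstream of it — the
    terminal-fragment signature. ``planted_ends`` maps gene id to a map of
    cell type to end positions (absolute coordinates, validated against the
    gene span); cells of a type share that type's ends. ``per_cell_ends``
    (gene id -> cell id -> positions) additionally plants ends in single
    cells, e.g. to emulate fully variable 3' UTR usage. A track dropped by
    ``dropout_rate`` is emitted empty (no detected expression).
    """
    rng = spec.stream(stream)
    gene_index = genes.set_index("gene_id")
    for gid, per_type in planted_ends.items():
        lo, hi = int(gene_index.at[gid, "start"]), int(gene_index.at[gid, "end"])
        for ctype, ends in per_type.items():
            for e in ends:
                if not lo <= e < hi:
                    raise ValidationError(
                        f"planted end {e} outside span [{lo}, {hi}) of "
                        f"gene {gid!r}")
    cells = [(f"{ct}_c{i + 1:02d}", ct)
             for ct in cell_types for i in range(n_cells_per_type)]
    tracks = {}
    for gid, row in gene_index.iterrows():
        lo, hi = int(row["start"]), int(row["end"])
        body_hi = int(row["annotated_end"])
        for cell_id, ctype in cells:
            if dropout_rate > 0 and rng.random() < dropout_rate:
                tracks[(gid, cell_id)] = ReadStartTrack(
                    gid, cell_id, row["chrom"], (lo, hi), row["strand"])
                continue
            breaks = rng.integers(lo, body_hi, fragments_per_track)
            keep_sense = np.ones(len(breaks), dtype=bool)
            keep_anti = np.ones(len(breaks), dtype=bool)
            if orphan_rate > 0:
                orphan = rng.random(len(breaks)) < orphan_rate
                which = rng.random(len(breaks)) < 0.5
                keep_sense &= ~(orphan & which)
                keep_anti &= ~(orphan & ~which)
            sense = breaks[keep_sense]
            anti = list(breaks[keep_anti])
            cell_extra = ((per_cell_ends or {}).get(gid, {})
                          .get(cell_id, ()))
            planted = list(planted_ends.get(gid, {}).get(ctype, ()))
            for e in list(planted) + list(cell_extra):  # 3' pile-up
                if not lo <= e < hi:
                    raise ValidationError(
                        f"planted end {e} outside span of gene {gid!r}")
                anti.extend(int(e) - rng.integers(0, 15, end_excess))
            tracks[(gid, cell_id)] = ReadStartTrack.from_positions(
                gid, cell_id, row["chrom"], (lo, hi), row["strand"],
                sense, anti)
    cells_df = pd.DataFrame(cells, columns=["cell_id", "cell_type"])
    return ReadStartData(tracks, genes.copy(), cells_df)


# ----------------------------------------------------------------------
# Annotation tables (half-life, categories, phenotypes)
# ----------------------------------------------------------------------

GENE_CATEGORIES = ("metabolism", "ribosome", "transcription_factor",
                   "ion_channel")


def simulate_annotations(
    spec: SyntheticSpec,
    hypervariable: np.ndarray | None = None,
    half_life_odds_ratio: float = 1.0,
    category_rate: float = 0.5,
    phenotype_rate: float = 0.2,
    half_life_log_mean: float = math.log(5.0),
    half_life_log_sd: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene half-life, functional-category and phenotype tables.

    Half-lives (hours) are log-normal. With ``half_life_odds_ratio`` > 1,
    hypervariable genes (mask from :func:`hypervariable_gene_mask` unless
    given) have their odds of landing in the fast-decay (bottom) tertile
    multiplied by that factor; an odds ratio of 1 plants no association.
    Every gene appears in every table exactly once (category may be the
    empty string for unannotated genes).
    """
    rng = spec.stream("annotations")
    n = spec.n_genes
    if hypervariable is None:
        hypervariable = hypervariable_gene_mask(spec)

    # tertile membership, with planted odds on the fast tertile
    probs = np.tile([1 / 3, 1 / 3, 1 / 3], (n, 1))
    if half_life_odds_ratio != 1.0:
        w = np.array([half_life_odds_ratio, 1.0, 1.0])
        probs[hypervariable] = w / w.sum()
    u = rng.random(n)
    tertile = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)  # 0=fast
    # half-life drawn inside the gene's tertile band of the log-normal
    band_u = (tertile + rng.random(n)) / 3.0
    from scipy.stats import norm
    half_life = np.exp(half_life_log_mean
                       + half_life_log_sd * norm.ppf(band_u))
    half_life_table = pd.DataFrame({"gene_id": spec.gene_ids,
                                    "half_life_h": half_life})

    annotated = rng.random(n) < category_rate
    cat_idx = rng.integers(0, len(GENE_CATEGORIES), n)
    category = np.where(annotated,
                        np.array(GENE_CATEGORIES, dtype=object)[cat_idx], "")
    category_table = pd.DataFrame({"gene_id": spec.gene_ids,
                                   "category": category})
    phenotype_table = pd.DataFrame({
        "gene_id": spec.gene_ids,
        "phenotype": (rng.random(n) < phenotype_rate).astype(int)})
    return half_life_table, category_table, phenotype_table
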