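"""Technical-variance control curve and reliable-expression thresholding.

The control curve summarises technical variance as a function of expression
level: per-gene sample variance of relative frequencies across dilution
replicates, ordered by mean relative frequency, smoothed by a sliding median
over a window of neighbouring genes (500 by default). Reliability criteria
then pick the expression level above which quantification is trustworthy:

1. at least half the genes in a window have no missing (zero) values across
   all dilution replicates, for every higher expression level;
2. the windowed median single-cell variance exceeds twice the control
   variance at matched expression level, for every higher level;
3. the windowed median Shapiro-Wilk p-value of the dilution replicates
   exceeds 0.01, for every higher level;
4. (diagnostic only) the breakpoint of a two-segment least-squares fit of
   log read depth against log expression rank.

The selected threshold is the most stringent (maximum) of criteria 1-3;
criterion 4 is reported but not used for selection, since no operational
rule for "consistent functional relationship" exists beyond the visual one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ThresholdUndefinedError
from .normalize import NormalizedMatrix

__all__ = [
    "ControlCurve",
    "ReliabilityThreshold",
    "build_control_curve",
    "evaluate_reliability_criteria",
    "threshold_to_molecules",
    "threshold_to_reads",
]


def _sliding_apply(values: np.ndarray, window: int, func,
                   edges: str = "truncate") -> np.ndarray:
    """Apply ``func`` over ~``window``-wide windows centred at each position.

    ``edges="truncate"`` shrinks the window symmetrically near the edges
    (radius min(w//2, i, n-1-i)); ``edges="shift"`` keeps the full window
    width and slides it inward instead, so edge estimates never collapse
    onto a handful of values."""
    n = len(values)
    half = window // 2
    out = np.empty(n)
    if edges == "truncate":
        for i in range(n):
            r = min(half, i, n - 1 - i)
            out[i] = func(values[i - r:i + r + 1])
    else:
        width = min(window, n)
        for i in range(n):
            lo = min(max(0, i - half), n - width)
            out[i] = func(values[lo:lo + width])
    return out


def _sliding_median(values: np.ndarray, window: int,
                    edges: str = "truncate") -> np.ndarray:
    return _sliding_apply(values, window, np.median, edges)


def _sliding_mean(values: np.ndarray, window: int,
                  edges: str = "truncate") -> np.ndarray:
    return _sliding_apply(values, window, np.mean, edges)


@dataclass
class ControlCurve:
    """Expression-ordered technical-variance baseline V_exp(x).

    ``x`` holds mean relative frequencies in ascending (gene-sorted) order,
    ``variance`` the per-gene sample variances in the same order, ``v_exp``
    the windowed medians. Lookup at an arbitrary expression level returns the
    value at the gene with nearest mean expression (piecewise constant, no
    interpolation); ties in ``x`` are grouped with the median of their
    windowed values.
    """

    gene_ids: np.ndarray
    x: np.ndarray
    variance: np.ndarray
    v_exp: np.ndarray
    window: int
    _ux: np.ndarray = field(init=False, repr=False)
    _uv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ux, inverse = np.unique(self.x, return_inverse=True)
        uv = np.empty(len(ux))
        for k in range(len(ux)):
            uv[k] = np.median(self.v_exp[inverse == k])
        self._ux = ux
        self._uv = uv

    def lookup(self, x) -> np.ndarray:
        """V_exp at the nearest tabulated expression level."""
        xq = np.atleast_1d(np.asarray(x, dtype=float))
        idx = np.searchsorted(self._ux, xq)
        idx = np.clip(idx, 1, len(self._ux) - 1)
        left = self._ux[idx - 1]
        right = self._ux[idx]
        choose_left = (xq - left) <= (right - xq)
        nearest = np.where(choose_left, idx - 1, idx)
        out = self._uv[nearest]
        return out if np.ndim(x) else float(out[0])


def build_control_curve(dilution: NormalizedMatrix,
                        window_genes: int = 500) -> ControlCurve:
    """Windowed-median technical variance from dilution replicates.

    Per-gene sample variance (ddof=1) of relative frequencies across
    replicates, genes sorted by mean relative frequency (ties broken by gene
    id for determinism), then a sliding median over ``window_genes``
    neighbours with symmetric edge truncation.
    """
    if window_genes < 3:
        raise ConfigurationError("window_genes must be at least 3")
    rf = dilution.relative_frequencies
    if rf.shape[1] < 2:
        raise ConfigurationError("need at least two dilution replicates")
    if window_genes > rf.shape[0]:
        raise ConfigurationError("window_genes exceeds the number of genes")
    mean = rf.mean(axis=1).to_numpy()
    var = rf.var(axis=1, ddof=1).to_numpy()
    order = np.lexsort((np.asarray(rf.index, dtype=object), mean))
    x = mean[order]
    v = var[order]
    v_exp = _sliding_median(v, window_genes)
    return ControlCurve(np.asarray(rf.index)[order], x, v, v_exp, window_genes)


# ----------------------------------------------------------------------
# Reliability criteria
# ----------------------------------------------------------------------

@dataclass
class ReliabilityThreshold:
    """Per-criterion expression thresholds (relative-frequency scale).

    ``criterion4`` is a diagnostic breakpoint only. ``selected`` combines
    criteria 1-3 as their maximum and raises if any of them was never
    satisfied (reported as +inf).
    """

    criterion1: float
    criterion2: float
    criterion3: float
    criterion4: float
    window: int

    def select(self, criteria=(1, 2, 3)) -> float:
        values = {1: self.criterion1, 2: self.criterion2,
                  3: self.criterion3}
        chosen = [values[c] for c in criteria]
        out = max(chosen)
        if not math.isfinite(out):
            bad = [c for c in criteria if not math.isfinite(values[c])]
            raise ThresholdUndefinedError(
                f"criteria {bad} were never satisfied; selected threshold "
                "is undefined")
        return out

    @property
    def selected(self) -> float:
        return self.select((1, 2, 3))


def _threshold_from_ok(x: np.ndarray, ok: np.ndarray) -> float:
    """Smallest expression level above which ``ok`` holds for all higher
    levels. Returns x[0] when always satisfied and +inf when the condition
    fails at the top of the expression range."""
    bad = np.flatnonzero(~ok)
    if bad.size == 0:
        return float(x[0])
    last = bad[-1]
    if last == len(x) - 1:
        return math.inf
    return float(x[last + 1])


def _shapiro_p(values: np.ndarray) -> float:
    if np.ptp(values) == 0:
        return 0.0  # degenerate: a constant sample is not normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(values).pvalue)


def _breakpoint_rank(depth: np.ndarray) -> int:
    """Two-segment least-squares breakpoint of log depth vs log rank.

    Depths sorted descending; returns the rank (1-based) at the segment
    boundary minimising total squared error. Coarse grid for large inputs.
    """
    d = np.sort(depth[depth > 0])[::-1]
    n = len(d)
    if n < 6:
        return n
    logy = np.log10(d)
    logx = np.log10(np.arange(1, n + 1))
    step = max(1, n // 200)
    candidates = range(3, n - 2, step)

    def sse(xs, ys):
        A = np.column_stack([np.ones_like(xs), xs])
        resid = ys - A @ np.linalg.lstsq(A, ys, rcond=None)[0]
        return float(resid @ resid)

    best, best_sse = n, np.inf
    for s in candidates:
        total = sse(logx[:s], logy[:s]) + sse(logx[s:], logy[s:])
        if total < best_sse:
            best_sse, best = total, s
    return best


def evaluate_reliability_criteria(
    dilution: NormalizedMatrix,
    cells: NormalizedMatrix,
    curve: ControlCurve,
    window: int | None = None,
    sw_alpha: float = 0.01,
    completeness_min: float = 0.5,
    variance_ratio: float = 2.0,
    with_breakpoint: bool = True,
) -> ReliabilityThreshold:
    """Evaluate the four reliability criteria against a control curve.

    Criteria 1 and 3 are computed on the dilution set ordered by dilution
    mean relative frequency; criterion 2 orders genes by single-cell mean
    relative frequency and requires the windowed median of the per-gene
    ratio (single-cell variance over control variance at that gene's
    matched expression level) to exceed ``variance_ratio``. Matching the
    control variance per gene before taking the median keeps both sides of
    the comparison at the same expression level. A criterion that is never
    satisfied is reported as +inf with a warning.
    """
    window = curve.window if window is None else window

    # --- dilution-side ordering --------------------------------------
    rf_d = dilution.relative_frequencies
    mean_d = rf_d.mean(axis=1).to_numpy()
    order_d = np.lexsort((np.asarray(rf_d.index, dtype=object), mean_d))
    x_d = mean_d[order_d]

    # Criteria windows keep full width at the edges (slid inward) so the
    # "for all higher levels" rule never fires on a near-empty window.
    complete = (dilution.counts.to_numpy() > 0).all(axis=1)[order_d]
    frac_complete = _sliding_mean(complete.astype(float), window, "shift")
    c1 = _threshold_from_ok(x_d, frac_complete >= completeness_min)

    values = rf_d.to_numpy()[order_d]
    sw_p = np.array([_shapiro_p(row) for row in values])
    med_p = _sliding_median(sw_p, window, "shift")
    c3 = _threshold_from_ok(x_d, med_p > sw_alpha)

    # --- cell-side ordering ------------------------------------------
    rf_c = cells.relative_frequencies
    mean_c = rf_c.mean(axis=1).to_numpy()
    order_c = np.lexsort((np.asarray(rf_c.index, dtype=object), mean_c))
    x_c = mean_c[order_c]
    var_c = rf_c.var(axis=1, ddof=1).to_numpy()[order_c]
    v_exp_matched = np.asarray(curve.lookup(x_c), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(v_exp_matched > 0, var_c / v_exp_matched, np.inf)
        ratio = np.where((v_exp_matched == 0) & (var_c == 0), 1.0, ratio)
    med_ratio = _sliding_median(ratio, window, "shift")
    c2 = _threshold_from_ok(x_c, med_ratio > variance_ratio)

    # --- diagnostic breakpoint ---------------------------------------
    if with_breakpoint:
        depth = dilution.normalized.mean(axis=1).to_numpy()
        rank = _breakpoint_rank(depth)
        positive = np.sort(mean_d[depth > 0])[::-1]
        c4 = float(positive[min(rank, len(positive)) - 1]) if len(positive) else math.nan
    else:
        c4 = math.nan

    for name, value in (("1", c1), ("2", c2), ("3", c3)):
        if not math.isfinite(value):
            warnings.warn(f"reliability criterion {name} was never satisfied "
                          "(threshold +inf)", stacklevel=2)
    return ReliabilityThreshold(c1, c2, c3, c4, window)


# ----------------------------------------------------------------------
# Threshold unit conversions
# ----------------------------------------------------------------------

def threshold_to_molecules(threshold: float,
                           molecules_per_cell: int = 150_000
                           ) -> tuple[float, int]:
    """Relative-frequency threshold expressed as input molecules.

    Returns the raw product and its nearest-integer report (e.g.
    6.3e-5 x 150,000 -> (9.45, 9))."""
    raw = threshold * molecules_per_cell
    return raw, int(round(raw))


def threshold_to_reads(threshold: float, library_size: int
                       ) -> tuple[float, int]:
    """Relative-frequency threshold expressed as reads at a library size."""
    raw = threshold * library_size
    return raw, int(round(raw))
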