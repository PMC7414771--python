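"""Structural correlation network construction.

A group network is the matrix of inter-regional Spearman correlations of
residualized thickness across that group's subjects, converted to edge
weights (absolute value, or positive-only as a sensitivity variant) and
sparsified at a threshold chosen by a random-matrix-theory (RMT) scan:
the cutoff at which the surviving matrix's eigenvalue nearest-neighbour
spacing distribution (NNSD) transitions from Wigner-Dyson (GOE, noise-like)
to Poisson (signal-like) statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

WEIGHT_MODES = ("absolute", "positive_only")


@dataclass
class CorrelationNetwork:
    """Undirected weighted graph over brain regions.

    ``weights`` is symmetric with zero diagonal and off-diagonal entries in
    [0, 1]; every retained edge weight is at least ``threshold``.
    """

    region_labels: list[str]
    weights: np.ndarray
    threshold: float
    weight_mode: str
    group: str = ""

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != (len(self.region_labels),) * 2:
            raise ValueError("weight matrix shape does not match region labels")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.region_labels)

    @property
    def total_weight(self) -> float:
        """W = half the sum of the (symmetric) weight matrix."""
        return float(self.weights.sum() / 2.0)

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum() // 2)

    def edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.weights, k=1))
        return pd.DataFrame(
            {
                "region_a": [self.region_labels[a] for a in i],
                "region_b": [self.region_labels[b] for b in j],
                "weight": self.weights[i, j],
            }
        )


def spearman_matrix(data: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation over columns (regions).

    Ties receive average ranks.  A constant column has undefined
    correlations; these are reported via a warning and returned as NaN for
    the caller to treat as zero weight.
    """
    x = np.asarray(data, float)
    if x.shape[0] < 3:
        raise ValueError("Spearman matrix needs at least 3 subjects")
    if np.isnan(x).any():
        raise ValueError("input contains missing values")
    constant = np.all(x == x[0], axis=0)
    ranks = stats.rankdata(x, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant region(s): correlations undefined",
            stacklevel=2,
        )
        rho[constant, :] = np.nan
        rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return rho


def to_weights(rho: np.ndarray, weight_mode: str = "absolute") -> np.ndarray:
    """Convert correlations to edge weights.

    ``absolute`` keeps |rho|; ``positive_only`` zeroes negative correlations
    (the negative-edge-removed sensitivity variant).  Undefined (NaN)
    correlations become zero weight; the diagonal is zeroed.
    """
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
    w = np.array(rho, float)
    nan_mask = np.isnan(w)
    if nan_mask.any():
        w[nan_mask] = 0.0
    if weight_mode == "absolute":
        w = np.abs(w)
    else:
        w = np.where(w > 0, w, 0.0)
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2.0


def build_network(
    weights: np.ndarray,
    threshold: float,
    weight_mode: str = "absolute",
    group: str = "",
    region_labels: list[str] | None = None,
) -> CorrelationNetwork:
    """Apply a threshold (closed rule: entries >= threshold are retained).

    Weights below the cutoff are set to zero; isolated nodes remain in the
    node set.  An all-empty network is an error advising a lower threshold.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    w = np.where(weights >= threshold, weights, 0.0)
    np.fill_diagonal(w, 0.0)
    if region_labels is None:
        region_labels = [f"r{i}" for i in range(w.shape[0])]
    if w.sum() == 0:
        raise ValueError(
            f"threshold {threshold} removed every edge; choose a lower threshold"
        )
    return CorrelationNetwork(
        region_labels=list(region_labels),
        weights=w,
        threshold=threshold,
        weight_mode=weight_mode,
        group=group,
    )


# ---------------------------------------------------------------------------
# RMT threshold scan
# ---------------------------------------------------------------------------

#: spacing histogram bin edges (last bin open-ended)
_NNSD_EDGES = np.arange(0.0, 3.01, 0.4)
_MIN_EIGENVALUES = 10  # below this the NNSD is meaningless


@dataclass
class RMTScan:
    """Result of a threshold scan with the NNSD decision statistics.

    ``table`` has one row per grid threshold with the number of distinct
    surviving eigenvalues, the chi-square distances of the unfolded NNSD to
    the Poisson and GOE (Wigner-Dyson) forms, and the Poisson
    goodness-of-fit p-value.  ``chosen_threshold`` is None when no grid
    point satisfies the decision rule.
    """

    table: pd.DataFrame
    chosen_threshold: float | None
    decision_rule: str = (
        "first-stable-poisson(p>=0.05, chi2_poisson<chi2_goe, run of 3 grid points)"
    )
    diagnostic: str = ""
    grid: np.ndarray = field(default_factory=lambda: np.array([]))


def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 0.951, 0.01), 2)


def _unfold_spectrum(eigs: np.ndarray, n_knots: int = 20) -> np.ndarray:
    """Unfold eigenvalues to unit mean spacing.

    A monotone (PCHIP) spline is fitted through ``n_knots`` quantile points
    of the empirical cumulative spectral density; the unfolded levels are
    n * F_fit(eigenvalue).
    """
    eigs = np.sort(eigs)
    n = len(eigs)
    k = min(n_knots, max(3, n // 2))
    idx = np.unique(np.linspace(0, n - 1, k).astype(int))
    x = eigs[idx]
    y = (idx + 1) / n
    # collapse duplicate abscissae (degenerate spectra)
    x, keep = np.unique(x, return_index=True)
    y = y[keep]
    if len(x) < 3:
        raise ValueError("spectrum too degenerate to unfold")
    f = PchipInterpolator(x, y, extrapolate=True)
    return n * f(eigs)


def nnsd_chi2(eigs: np.ndarray) -> tuple[float, float, float]:
    """Chi-square distances of the NNSD to the Poisson and GOE laws.

    Returns ``(chi2_poisson, chi2_goe, p_poisson)`` where ``p_poisson`` is
    the goodness-of-fit p-value against the Poisson (exponential) spacing
    law.  Eigenvalues are deduplicated before unfolding so that massive
    degeneracies (many identical eigenvalues after thresholding) do not
    masquerade as zero spacings.
    """
    eigs = np.unique(np.round(np.sort(eigs), 8))
    if len(eigs) < _MIN_EIGENVALUES:
        raise ValueError(f"need >= {_MIN_EIGENVALUES} distinct eigenvalues")
    unfolded = _unfold_spectrum(eigs)
    s = np.diff(np.sort(unfolded))
    s = s / s.mean()

    edges = np.concatenate([_NNSD_EDGES, [np.inf]])
    observed, _ = np.histogram(s, bins=edges)
    lo, hi = edges[:-1], edges[1:]
    # Poisson spacing law: P(s) = exp(-s)
    exp_pois = (np.exp(-lo) - np.exp(-np.where(np.isinf(hi), 700, hi))) * len(s)
    # GOE (Wigner surmise): P(s) = (pi s / 2) exp(-pi s^2 / 4)
    goe_cdf = lambda t: 1.0 - np.exp(-np.pi * np.minimum(t, 1e6) ** 2 / 4.0)
    exp_goe = (goe_cdf(hi) - goe_cdf(lo)) * len(s)

    def merged_chi2(obs: np.ndarray, exp: np.ndarray, min_exp: float = 3.0):
        o, e = [], []
        acc_o = acc_e = 0.0
        for oi, ei in zip(obs, exp):
            acc_o += oi
            acc_e += ei
            if acc_e >= min_exp:
                o.append(acc_o)
                e.append(acc_e)
                acc_o = acc_e = 0.0
        if acc_e > 0 and e:
            o[-1] += acc_o
            e[-1] += acc_e
        o, e = np.array(o), np.array(e)
        if len(e) < 2:
            return np.inf, 1
        return float(np.sum((o - e) ** 2 / e)), len(e) - 1

    chi2_p, dof_p = merged_chi2(observed, exp_pois)
    chi2_g, _ = merged_chi2(observed, exp_goe)
    p_pois = float(stats.chi2.sf(chi2_p, df=dof_p)) if np.isfinite(chi2_p) else 0.0
    return chi2_p, chi2_g, p_pois


def rmt_threshold_scan(
    weights: np.ndarray,
    grid: np.ndarray | None = None,
    p_threshold: float = 0.05,
    sustain_points: int = 3,
) -> RMTScan:
    """Scan thresholds and pick the Wigner-Dyson-to-Poisson transition point.

    For each grid value the weight matrix entries below it are zeroed (unit
    diagonal restored), the spectrum is unfolded, and the NNSD is compared
    with the Poisson and GOE laws.  The chosen threshold is the smallest
    grid value opening a run of ``sustain_points`` consecutive defined grid
    values at which the Poisson law fits better than GOE with Poisson
    goodness-of-fit p >= ``p_threshold`` (a stable transition, robust to a
    single noisy grid point; at much larger cutoffs the network fragments
    and the statistics lose meaning, so sustainment is only required
    locally).
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0) or grid[0] < 0 or grid[-1] >= 1:
        raise ValueError("grid must be ascending within [0, 1)")
    if not np.array_equal(weights, weights.T):
        raise ValueError("weight matrix must be symmetric")

    n_nodes = weights.shape[0]
    rows = []
    for t in grid:
        surv = np.where(np.abs(weights) >= t, weights, 0.0)
        np.fill_diagonal(surv, 1.0)
        n_edges = int((np.triu(surv, 1) != 0).sum())
        off = surv - np.diag(np.diag(surv))
        n_connected = int((np.abs(off).sum(axis=0) > 0).sum())
        eigs = np.linalg.eigvalsh(surv)
        n_distinct = len(np.unique(np.round(eigs, 8)))
        row = {
            "threshold": t,
            "n_edges": n_edges,
            "n_connected_nodes": n_connected,
            "n_distinct_eigs": n_distinct,
            "chi2_poisson": np.nan,
            "chi2_goe": np.nan,
            "p_poisson": np.nan,
            "poisson_like": False,
            "defined": False,
            # a cutoff that isolates most nodes has destroyed the graph; such
            # grid points cannot be selected
            "eligible": 2 * n_connected >= n_nodes,
        }
        try:
            chi2_p, chi2_g, p_pois = nnsd_chi2(eigs)
            row.update(
                chi2_poisson=chi2_p,
                chi2_goe=chi2_g,
                p_poisson=p_pois,
                poisson_like=bool(chi2_p < chi2_g and p_pois >= p_threshold),
                defined=True,
            )
        except ValueError:
            pass
        rows.append(row)
    table = pd.DataFrame(rows)

    chosen = None
    defined = (table["defined"].to_numpy() & table["eligible"].to_numpy()).astype(bool)
    ok = (table["poisson_like"].to_numpy() & defined).astype(bool)
    run = min(sustain_points, int(defined.sum())) or 1
    sustained = np.zeros(len(grid), bool)
    for i in range(len(grid)):
        if not ok[i]:
            continue
        # next `run` defined grid points starting here must all qualify
        ahead = [j for j in range(i, len(grid)) if defined[j]][:run]
        if len(ahead) == run and all(ok[j] for j in ahead):
            sustained[i] = True
    hits = np.nonzero(sustained)[0]
    diagnostic = ""
    if len(hits):
        chosen = float(grid[hits[0]])
    else:
        if not defined.any():
            diagnostic = "degenerate spectrum at every threshold; no transition found"
        else:
            diagnostic = "no sustained Wigner-Dyson-to-Poisson transition on the grid"
    return RMTScan(table=table, chosen_threshold=chosen, diagnostic=diagnostic, grid=grid)
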