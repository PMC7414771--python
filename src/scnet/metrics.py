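"""Global weighted graph measures of a structural correlation network.

Five scalars summarise each group network:

- ``avgSPL``  - average shortest path length over reachable node pairs,
  with edge lengths 1/w (integration);
- ``avgLCC``  - average Barrat weighted clustering coefficient (segregation);
- ``avgLEFF`` - average weighted local efficiency (segregation);
- ``SW``      - small-worldness, (avgLCC/avgLCC_rand)/(avgSPL/avgSPL_rand)
  against weight-permuted null networks;
- ``Q``       - weighted modularity maximized by simulated annealing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._sa import sa_kernel
from .network import CorrelationNetwork

MEASURE_NAMES = ("avgSPL", "avgLCC", "avgLEFF", "SW", "Q")


@dataclass(frozen=True)
class SAParams:
    """Simulated-annealing schedule for modularity maximization.

    ``moves_factor`` scales the number of proposals per temperature stage
    (``moves_factor * N**2``); ``p_single`` is the probability of a
    single-node move (the remainder splits evenly between module merges and
    random bipartition splits).
    """

    t0: float = 1.0
    cooling: float = 0.995
    tmin: float = 1e-5
    moves_factor: float = 1.0
    p_single: float = 0.85
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.cooling < 1):
            raise ValueError("cooling must be in (0, 1)")
        if self.tmin <= 0 or self.t0 <= self.tmin:
            raise ValueError("need t0 > tmin > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


#: lighter schedule for inner loops (permutation tests) where the same
#: optimizer is applied symmetrically to observed and null networks
FAST_SA = SAParams(t0=0.02, cooling=0.9, tmin=1e-5, moves_factor=0.5, n_restarts=1)


@dataclass
class GlobalMeasures:
    """The five global measures of one network plus null-model summaries."""

    avgSPL: float
    avgLCC: float
    avgLEFF: float
    SW: float
    Q: float
    avgSPL_rand: float
    avgLCC_rand: float
    n_null: int
    partition: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    unreachable_pairs: int = 0

    def as_vector(self) -> np.ndarray:
        return np.array([self.avgSPL, self.avgLCC, self.avgLEFF, self.SW, self.Q])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(MEASURE_NAMES, map(float, self.as_vector())))


def _weights(net) -> np.ndarray:
    return net.weights if isinstance(net, CorrelationNetwork) else np.asarray(net, float)


def distance_matrix(net) -> np.ndarray:
    """All-pairs shortest-path distances with edge lengths 1/w.

    Unreachable pairs are ``inf``; the diagonal is 0.  Small graphs use a
    vectorised Floyd-Warshall; larger ones scipy's Dijkstra.
    """
    w = _weights(net)
    n = w.shape[0]
    if n <= 64:
        d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        np.fill_diagonal(d, 0.0)
        for k in range(n):
            np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
        return d
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def avg_shortest_path_length(net, dist: np.ndarray | None = None) -> float:
    """Mean shortest-path distance over unordered reachable node pairs."""
    d = distance_matrix(net) if dist is None else dist
    off = d[np.triu_indices_from(d, k=1)]
    reachable = np.isfinite(off)
    if not reachable.any():
        raise ValueError("network has no reachable node pair")
    return float(off[reachable].mean())


def degrees_strengths(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree k_i (count of nonzero incident weights) and strength s_i."""
    b = (w > 0).astype(float)
    return b.sum(axis=1), w.sum(axis=1)


def weighted_clustering(net) -> tuple[np.ndarray, float]:
    """Barrat weighted clustering coefficient per node and its average.

    C_i = sum over ordered neighbour pairs (j, h) with a closing edge
    (w_jh > 0) of (w_ij + w_ih)/2, normalised by s_i (k_i - 1);
    0 for nodes with k_i <= 1.  The average divides by N over all nodes.
    """
    w = _weights(net)
    b = (w > 0).astype(float)
    k, s = degrees_strengths(w)
    # sum_{j,h} [(w_ij + w_ih)/2] B_ij B_ih B_jh  ==  sum_j w_ij (B@B)_ij
    common = b @ b
    num = (w * common).sum(axis=1)
    c = np.zeros(w.shape[0])
    ok = k >= 2
    c[ok] = num[ok] / (s[ok] * (k[ok] - 1.0))
    return c, float(c.mean())


def local_efficiency(
    net, dist: np.ndarray | None = None, convention: str = "full_network"
) -> tuple[np.ndarray, float]:
    """Weighted local efficiency per node and its average.

    E_loc(i) = sum over ordered neighbour pairs (j, h) of 1/d_jh, divided
    by k_i (k_i - 1); 0 when k_i <= 1, and unreachable pairs contribute 0.

    ``convention`` fixes where d_jh is measured: ``full_network`` (default,
    the literal reading of the printed formula) takes shortest paths in the
    whole network; ``neighborhood_subgraph`` restricts paths to the
    subgraph induced by nn(i).
    """
    if convention not in ("full_network", "neighborhood_subgraph"):
        raise ValueError("unknown local-efficiency convention")
    w = _weights(net)
    n = w.shape[0]
    k, _ = degrees_strengths(w)
    e = np.zeros(n)
    if convention == "full_network":
        d = distance_matrix(net) if dist is None else dist
        with np.errstate(divide="ignore"):
            dinv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        for i in range(n):
            if k[i] < 2:
                continue
            nn = np.nonzero(w[i] > 0)[0]
            e[i] = dinv[np.ix_(nn, nn)].sum() / (k[i] * (k[i] - 1.0))
    else:
        for i in range(n):
            if k[i] < 2:
                continue
            nn = np.nonzero(w[i] > 0)[0]
            sub = w[np.ix_(nn, nn)]
            d = distance_matrix(sub)
            with np.errstate(divide="ignore"):
                dinv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
            e[i] = dinv.sum() / (k[i] * (k[i] - 1.0))
    return e, float(e.mean())


def weight_permuted_nulls(net, n_null: int = 100, seed=None) -> list[np.ndarray]:
    """Null weight matrices: same edge topology, permuted edge weights."""
    w = _weights(net)
    iu, ju = np.nonzero(np.triu(w, k=1))
    if len(iu) < 2:
        import warnings

        warnings.warn("single-edge network: nulls identical to input", stacklevel=2)
    vals = w[iu, ju]
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(n_null):
        perm = rng.permutation(vals)
        m = np.zeros_like(w)
        m[iu, ju] = perm
        nulls.append(m + m.T)
    return nulls


def small_worldness(
    net, n_null: int = 100, seed=None, return_null_means: bool = False
):
    """SW = (avgLCC/avgLCC_rand) / (avgSPL/avgSPL_rand) over weight-permuted nulls."""
    spl = avg_shortest_path_length(net)
    _, lcc = weighted_clustering(net)
    spl_r, lcc_r = [], []
    for m in weight_permuted_nulls(net, n_null=n_null, seed=seed):
        spl_r.append(avg_shortest_path_length(m))
        lcc_r.append(weighted_clustering(m)[1])

    def _mean(vals):
        # mean of a constant list is that constant exactly (all-equal-weight
        # networks must give SW = 1 with no rounding drift)
        return vals[0] if min(vals) == max(vals) else float(np.mean(vals))

    spl_rand = _mean(spl_r)
    lcc_rand = _mean(lcc_r)
    if lcc_rand <= 0 or spl_rand <= 0:
        raise ValueError(
            f"null ensemble has zero clustering or path length "
            f"(avgLCC_rand={lcc_rand}, avgSPL_rand={spl_rand})"
        )
    sw = (lcc / lcc_rand) / (spl / spl_rand)
    if return_null_means:
        return sw, spl_rand, lcc_rand
    return sw


def modularity_q(net, labels) -> float:
    """Weighted modularity Q of a given partition.

    Q = (1/2W) * sum_ij (w_ij - s_i s_j / 2W) delta(c_i, c_j), summed over
    ordered pairs (w_ii = 0).
    """
    w = _weights(net)
    labels = np.asarray(labels)
    if len(labels) != w.shape[0]:
        raise ValueError("partition must assign every node a module")
    two_w = w.sum()
    if two_w <= 0:
        raise ValueError("network has no edge weight")
    q = 0.0
    s = w.sum(axis=1)
    for m in np.unique(labels):
        idx = labels == m
        win = w[np.ix_(idx, idx)].sum()  # ordered pairs within module
        sm = s[idx].sum()
        q += win / two_w - (sm / two_w) ** 2
    return float(q)


def maximize_modularity_sa(
    net, sa_params: SAParams | None = None, seed=None
) -> tuple[np.ndarray, float]:
    """Best-of-restarts simulated-annealing search for the maximum-Q partition.

    The result is never below the single-module or the all-singletons Q,
    which are evaluated as baselines.
    """
    w = _weights(net)
    n = w.shape[0]
    if w.sum() <= 0:
        raise ValueError("network has no edge weight")
    params = sa_params or SAParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kernel_seeds = ss.generate_state(params.n_restarts) % np.uint32(2**31 - 1)
    moves = max(n, int(params.moves_factor * n * n))

    # closed-form baselines: single module has Q = 0 exactly; singletons
    # have Q = -sum (s_i/2W)^2
    s = w.sum(axis=1)
    two_w = s.sum()
    best_labels = np.zeros(n, dtype=np.int64)
    best_q = 0.0
    singleton_q = -float(((s / two_w) ** 2).sum())
    if singleton_q > best_q:
        best_labels, best_q = np.arange(n), singleton_q

    for ks in kernel_seeds:
        labels, q = sa_kernel(
            np.ascontiguousarray(w, dtype=np.float64),
            int(ks),
            params.t0,
            params.cooling,
            params.tmin,
            moves,
            params.p_single,
        )
        if q > best_q + 1e-13:
            best_labels, best_q = labels, q
    # report Q recomputed from the partition (guards against drift in the
    # kernel's incremental bookkeeping)
    return np.asarray(best_labels), modularity_q(w, best_labels)


def global_measures(
    net,
    n_null: int = 100,
    sa_params: SAParams | None = None,
    seed=None,
    measures: tuple[str, ...] = MEASURE_NAMES,
) -> GlobalMeasures:
    """Compute the five global measures of one network.

    ``seed`` drives both the weight-permuted small-world nulls and the
    annealing restarts (via independent substreams).  ``measures`` may
    restrict the computation (skipping the null ensemble and the annealing
    when SW / Q are not requested); omitted measures are NaN.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sw_ss, sa_ss = ss.spawn(2)
    d = distance_matrix(net)
    spl = avg_shortest_path_length(net, dist=d)
    _, lcc = weighted_clustering(net)
    leff = np.nan
    if "avgLEFF" in measures:
        _, leff = local_efficiency(net, dist=d)
    sw = spl_rand = lcc_rand = np.nan
    if "SW" in measures:
        sw, spl_rand, lcc_rand = small_worldness(
            net, n_null=n_null, seed=sw_ss, return_null_means=True
        )
    partition, q = np.array([], dtype=int), np.nan
    if "Q" in measures:
        partition, q = maximize_modularity_sa(net, sa_params=sa_params, seed=sa_ss)
    off = d[np.triu_indices_from(d, k=1)]
    return GlobalMeasures(
        avgSPL=spl,
        avgLCC=lcc,
        avgLEFF=leff,
        SW=sw,
        Q=q,
        avgSPL_rand=spl_rand,
        avgLCC_rand=lcc_rand,
        n_null=n_null,
        partition=partition,
        unreachable_pairs=int((~np.isfinite(off)).sum()),
    )
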