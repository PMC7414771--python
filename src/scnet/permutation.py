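"""Subject-permutation test of group differences in network measures.

The null hypothesis is that the inter-regional correlation pattern is the
same in both groups.  Subjects are randomly re-partitioned into
pseudo-groups of the original sizes, both pseudo-networks are rebuilt
through the full construction pipeline, and the five measure differences
(Met carriers minus Val homozygotes by convention) form the null
distributions.  One-sided p-values are plain indicator means with strict
inequalities (tpc = 1000 by default); Bonferroni control uses
0.05 / 5 = 0.01 per test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    MEASURE_NAMES,
    FAST_SA,
    GlobalMeasures,
    SAParams,
    global_measures,
)
from .network import build_network, rmt_threshold_scan, spearman_matrix, to_weights


@dataclass(frozen=True)
class NetworkPipelineConfig:
    """Configuration of the per-group network construction + measurement.

    ``threshold_policy`` is ``"rmt"`` (re-run the RMT scan on every network,
    including inside each permutation) or ``"fixed"`` (use
    ``fixed_threshold`` throughout).  ``rmt_fallback_threshold`` is used
    when a scan finds no transition.
    """

    weight_mode: str = "absolute"
    threshold_policy: str = "rmt"
    fixed_threshold: float = 0.0
    rmt_grid: np.ndarray | None = None
    rmt_fallback_threshold: float = 0.3
    n_null: int = 100
    sa_params: SAParams = field(default_factory=SAParams)
    leff_convention: str = "full_network"
    measures: tuple[str, ...] = MEASURE_NAMES

    def __post_init__(self) -> None:
        if self.threshold_policy not in ("rmt", "fixed"):
            raise ValueError("threshold_policy must be 'rmt' or 'fixed'")


def observed_difference(
    measures_met: GlobalMeasures, measures_val: GlobalMeasures
) -> np.ndarray:
    """Elementwise Met-carrier minus Val-homozygote measure vector."""
    if measures_met.n_null != measures_val.n_null:
        raise ValueError("measure sets computed under different configurations")
    return measures_met.as_vector() - measures_val.as_vector()


def bonferroni_alpha(familywise: float = 0.05, n_tests: int = 5) -> float:
    """Per-test significance level under Bonferroni control."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return familywise / n_tests


def permute_groups(
    n_subjects: int, group_sizes: tuple[int, int], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random partition of subject indices into the two stated sizes."""
    n_a, n_b = group_sizes
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if n_a + n_b != n_subjects:
        raise ValueError(
            f"group sizes {group_sizes} do not sum to subject count {n_subjects}"
        )
    perm = rng.permutation(n_subjects)
    return np.sort(perm[:n_a]), np.sort(perm[n_a:])


def measures_for_rows(
    residuals: np.ndarray,
    rows: np.ndarray,
    config: NetworkPipelineConfig,
    seed,
    group: str = "",
) -> GlobalMeasures:
    """Run one row subset through network construction and measurement."""
    rho = spearman_matrix(residuals[rows])
    w = to_weights(rho, config.weight_mode)
    if config.threshold_policy == "rmt":
        scan = rmt_threshold_scan(w, grid=config.rmt_grid)
        threshold = (
            scan.chosen_threshold
            if scan.chosen_threshold is not None
            else config.rmt_fallback_threshold
        )
    else:
        threshold = config.fixed_threshold
    net = build_network(w, threshold, weight_mode=config.weight_mode, group=group)
    return global_measures(
        net,
        n_null=config.n_null,
        sa_params=config.sa_params,
        seed=seed,
        measures=config.measures,
    )


@dataclass
class PermutationResult:
    """Observed and null measure differences with one-sided p-values."""

    tpc: int
    observed: np.ndarray  # 5-vector, Met - Val
    simulated: np.ndarray  # tpc x 5 null differences
    p_greater: np.ndarray
    p_less: np.ndarray
    alpha_per_test: float
    significant: np.ndarray  # one-sided in the direction of the observed diff
    p_directional: np.ndarray
    seed: int | None
    redraws: int
    smoothed: bool
    config: NetworkPipelineConfig

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_diff": self.observed,
                "p_greater": self.p_greater,
                "p_less": self.p_less,
                "p_directional": self.p_directional,
                "significant": self.significant,
            },
            index=pd.Index(MEASURE_NAMES, name="measure"),
        )


def permutation_test(
    residuals,
    group_labels,
    met_group: str,
    val_group: str,
    tpc: int = 1000,
    config: NetworkPipelineConfig | None = None,
    seed: int | None = None,
    smoothed: bool = False,
    familywise_alpha: float = 0.05,
    max_redraws: int = 100,
    directions: dict[str, str] | None = None,
) -> PermutationResult:
    """Full-pipeline permutation test of the five network measures.

    Each permutation re-partitions subjects into pseudo-groups of the
    original sizes and rebuilds both networks under ``config``.  A
    permutation whose thresholded network ends up empty is redrawn (counted
    in ``redraws``).  With ``smoothed=True`` p-values are (b+1)/(tpc+1)
    instead of the plain indicator mean.  ``directions`` may pre-register
    the one-sided alternative per measure ({"avgLEFF": "greater", ...});
    measures without an entry use the direction of the observed difference.
    """
    if config is None:
        config = NetworkPipelineConfig()
    resid = np.asarray(
        residuals if not hasattr(residuals, "values") else residuals.values, float
    )
    group_labels = np.asarray(group_labels)
    met_rows = np.nonzero(group_labels == met_group)[0]
    val_rows = np.nonzero(group_labels == val_group)[0]
    if len(met_rows) + len(val_rows) != len(group_labels):
        raise ValueError("group labels contain values other than the two groups")
    if min(len(met_rows), len(val_rows)) < 3:
        raise ValueError("each group needs at least 3 subjects for Spearman networks")
    if tpc < 1:
        raise ValueError("tpc must be >= 1")
    sizes = (len(val_rows), len(met_rows))

    ss = np.random.SeedSequence(seed)
    obs_ss, perm_draw_ss, *perm_ss = ss.spawn(2 + tpc)
    obs_met_ss, obs_val_ss = obs_ss.spawn(2)
    rng = np.random.default_rng(perm_draw_ss)

    m_met = measures_for_rows(resid, met_rows, config, obs_met_ss, group=met_group)
    m_val = measures_for_rows(resid, val_rows, config, obs_val_ss, group=val_group)
    observed = observed_difference(m_met, m_val)

    simulated = np.empty((tpc, 5))
    redraws = 0
    for t in range(tpc):
        sub_met, sub_val = perm_ss[t].spawn(2)
        for attempt in range(max_redraws + 1):
            pseudo_val, pseudo_met = permute_groups(len(group_labels), sizes, rng)
            try:
                pm = measures_for_rows(resid, pseudo_met, config, sub_met)
                pv = measures_for_rows(resid, pseudo_val, config, sub_val)
                break
            except ValueError:
                redraws += 1
                if attempt == max_redraws:
                    raise
        simulated[t] = pm.as_vector() - pv.as_vector()

    greater = (simulated > observed[None, :]).sum(axis=0)
    less = (simulated < observed[None, :]).sum(axis=0)
    if smoothed:
        p_greater = (greater + 1) / (tpc + 1)
        p_less = (less + 1) / (tpc + 1)
    else:
        p_greater = greater / tpc
        p_less = less / tpc

    alpha = bonferroni_alpha(familywise_alpha, len(MEASURE_NAMES))
    p_directional = np.where(observed >= 0, p_greater, p_less)
    if directions:
        for name, side in directions.items():
            if name not in MEASURE_NAMES or side not in ("greater", "less"):
                raise ValueError(f"bad direction entry {name!r}: {side!r}")
            i = MEASURE_NAMES.index(name)
            p_directional[i] = p_greater[i] if side == "greater" else p_less[i]
    significant = p_directional < alpha

    return PermutationResult(
        tpc=tpc,
        observed=observed,
        simulated=simulated,
        p_greater=p_greater,
        p_less=p_less,
        alpha_per_test=alpha,
        significant=significant,
        p_directional=p_directional,
        seed=seed,
        redraws=redraws,
        smoothed=smoothed,
        config=config,
    )
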