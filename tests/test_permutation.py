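"""Subject-permutation comparison: split sampling, p-value formulas,
determinism and degenerate cases."""

from itertools import combinations

import numpy as np
import pytest

from scnet.metrics import FAST_SA, GlobalMeasures, MEASURE_NAMES
from scnet.permutation import (
    NetworkPipelineConfig,
    bonferroni_alpha,
    measures_for_rows,
    observed_difference,
    permutation_test,
    permute_groups,
)
from scnet.synthetic import CohortConfig, MET_CARRIER, VAL_HOMOZYGOTE, generate_cohort
from scnet.preprocess import residualize_all


def _measures(vec, n_null=10):
    return GlobalMeasures(*vec, avgSPL_rand=1.0, avgLCC_rand=1.0, n_null=n_null)


def toy_residuals(seed=0, n_per=12, n_regions=8):
    cfg = CohortConfig(
        n_subjects_per_group=(n_per, n_per),
        n_regions=n_regions,
        genotype_probs=(0.5, 0.4, 0.1),
        r_within={VAL_HOMOZYGOTE: 0.4, MET_CARRIER: 0.4},
        r_between={VAL_HOMOZYGOTE: 0.15, MET_CARRIER: 0.15},
        r_homotopic={VAL_HOMOZYGOTE: 0.7, MET_CARRIER: 0.7},
    )
    cohort = generate_cohort(cfg, seed=seed)
    resid = residualize_all(cohort.thickness, cohort.table["age"], cohort.table["gender"])
    return resid.residuals, cohort.table["group"].to_numpy()


FIXED_CFG = NetworkPipelineConfig(
    threshold_policy="fixed", fixed_threshold=0.25, n_null=10, sa_params=FAST_SA
)


class TestObservedDifference:
    def test_elementwise_met_minus_val(self):
        met = _measures([1.657, 0.715, 0.627, 1.409, 0.119])
        val = _measures([1.814, 0.551, 0.484, 0.997, 0.190])
        diff = observed_difference(met, val)
        assert diff[2] == pytest.approx(0.143)  # the headline avgLEFF gap
        assert np.allclose(diff, met.as_vector() - val.as_vector())

    def test_identical_inputs_zero_and_antisymmetry(self):
        a = _measures([1.0, 0.5, 0.4, 1.1, 0.2])
        b = _measures([1.2, 0.6, 0.3, 0.9, 0.1])
        assert np.allclose(observed_difference(a, a), 0.0)
        assert np.allclose(
            observed_difference(a, b), -observed_difference(b, a)
        )

    def test_configuration_mismatch_rejected(self):
        a = _measures([1, 1, 1, 1, 0], n_null=10)
        b = _measures([1, 1, 1, 1, 0], n_null=50)
        with pytest.raises(ValueError, match="configuration"):
            observed_difference(a, b)


class TestBonferroni:
    @pytest.mark.parametrize(
        "fw, k, expected", [(0.05, 5, 0.01), (0.05, 1, 0.05), (0.10, 4, 0.025)]
    )
    def test_values(self, fw, k, expected):
        assert bonferroni_alpha(fw, k) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestPermuteGroups:
    def test_partition_properties(self):
        rng = np.random.default_rng(0)
        a, b = permute_groups(49, (16, 33), rng)
        assert len(a) == 16 and len(b) == 33
        assert len(np.intersect1d(a, b)) == 0
        assert np.array_equal(np.sort(np.concatenate([a, b])), np.arange(49))

    def test_degenerate_sizes_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            permute_groups(6, (0, 6), rng)
        with pytest.raises(ValueError):
            permute_groups(6, (2, 3), rng)

    def test_uniform_over_all_splits(self):
        # C(6,3) = 20 distinct splits, each should appear with freq 0.05
        rng = np.random.default_rng(1)
        counts = {frozenset(c): 0 for c in combinations(range(6), 3)}
        n_draw = 2000
        for _ in range(n_draw):
            a, _ = permute_groups(6, (3, 3), rng)
            counts[frozenset(a.tolist())] += 1
        freqs = np.array(list(counts.values())) / n_draw
        assert np.all(np.abs(freqs - 0.05) <= 0.02)


class TestPermutationTest:
    def test_p_values_on_grid_and_complementarity(self):
        resid, groups = toy_residuals(seed=1)
        res = permutation_test(
            resid, groups, met_group=MET_CARRIER, val_group=VAL_HOMOZYGOTE,
            tpc=50, config=FIXED_CFG, seed=11,
        )
        grid = np.arange(51) / 50
        for p in np.concatenate([res.p_greater, res.p_less]):
            assert np.any(np.isclose(p, grid))
        ties = 1.0 - res.p_greater - res.p_less
        assert np.all(ties >= -1e-12)  # p_greater + p_less = 1 - ties/tpc

    def test_smoothed_p_has_floor(self):
        resid, groups = toy_residuals(seed=2)
        res = permutation_test(
            resid, groups, met_group=MET_CARRIER, val_group=VAL_HOMOZYGOTE,
            tpc=20, config=FIXED_CFG, seed=3, smoothed=True,
        )
        assert np.all(res.p_greater >= 1 / 21 - 1e-12)
        assert np.all(res.p_less >= 1 / 21 - 1e-12)

    def test_bit_reproducible_and_seed_sensitive(self):
        resid, groups = toy_residuals(seed=3, n_per=8)
        kw = dict(met_group=MET_CARRIER, val_group=VAL_HOMOZYGOTE,
                  tpc=20, config=FIXED_CFG)
        a = permutation_test(resid, groups, seed=5, **kw)
        b = permutation_test(resid, groups, seed=5, **kw)
        c = permutation_test(resid, groups, seed=6, **kw)
        assert np.array_equal(a.simulated, b.simulated)
        assert np.array_equal(a.p_greater, b.p_greater)
        assert not np.array_equal(a.simulated, c.simulated)

    def test_directional_significance_uses_observed_sign(self):
        resid, groups = toy_residuals(seed=4)
        res = permutation_test(
            resid, groups, met_group=MET_CARRIER, val_group=VAL_HOMOZYGOTE,
            tpc=40, config=FIXED_CFG, seed=9,
        )
        for i in range(5):
            expected = res.p_greater[i] if res.observed[i] >= 0 else res.p_less[i]
            assert res.p_directional[i] == expected
        assert res.alpha_per_test == pytest.approx(0.01)

    def test_preregistered_direction_overrides_observed_sign(self):
        resid, groups = toy_residuals(seed=6)
        kw = dict(met_group=MET_CARRIER, val_group=VAL_HOMOZYGOTE,
                  tpc=30, config=FIXED_CFG, seed=12)
        res = permutation_test(resid, groups,
                               directions={"avgLEFF": "greater", "Q": "less"}, **kw)
        i, j = MEASURE_NAMES.index("avgLEFF"), MEASURE_NAMES.index("Q")
        assert res.p_directional[i] == res.p_greater[i]
        assert res.p_directional[j] == res.p_less[j]
        with pytest.raises(ValueError, match="direction"):
            permutation_test(resid, groups, directions={"avgLEFF": "up"}, **kw)

    def test_small_groups_rejected(self):
        resid, groups = toy_residuals(seed=5, n_per=4)
        bad = groups.copy()
        bad[:] = MET_CARRIER
        bad[:2] = VAL_HOMOZYGOTE
        with pytest.raises(ValueError, match="at least 3"):
            permutation_test(
                resid, bad, met_group=MET_CARRIER, val_group=VAL_HOMOZYGOTE,
                tpc=5, config=FIXED_CFG, seed=0,
            )

    def test_null_p_values_roughly_uniform(self):
        # exchangeable groups: p_greater for avgSPL should be uniform on its grid
        cfg = NetworkPipelineConfig(
            threshold_policy="fixed", fixed_threshold=0.2, n_null=5,
            sa_params=FAST_SA, measures=("avgSPL", "avgLCC"),
        )
        ps = []
        for r in range(100):
            resid, groups = toy_residuals(seed=100 + r, n_per=8)
            res = permutation_test(
                resid, groups, met_group=MET_CARRIER, val_group=VAL_HOMOZYGOTE,
                tpc=50, config=cfg, seed=500 + r,
            )
            ps.append(res.p_greater[0])
        from scipy import stats

        # discreteness of the tpc=50 grid inflates the KS distance by ~0.01
        assert stats.kstest(ps, "uniform").pvalue > 0.01
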