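"""Permutation inference: sign-flip oracle, FWE machinery, GPD tail, two-sample."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lesionnet.permutation import (
    GroupDesign,
    PermutationConfig,
    _weighted_welch_t,
    fit_gpd_tail,
    gpd_tail_pvalue,
    one_sample_permutation,
    one_sample_permutation_matrix,
    significant_mask,
    two_sample_permutation_matrix,
)
from lesionnet.volumes import BinaryMask, VolumeError, VolumeGrid, insert


@pytest.fixture
def tiny_mask():
    grid = VolumeGrid((3, 3, 3), np.eye(4))
    data = np.zeros(grid.shape, bool)
    data[0, 0, 0] = True
    return BinaryMask(grid, data)


def _flat_mask(n_voxels: int) -> BinaryMask:
    grid = VolumeGrid((n_voxels, 1, 1), np.eye(4))
    return BinaryMask(grid, np.ones(grid.shape, bool))


def exhaustive_sign_flip_p(mat: np.ndarray) -> np.ndarray:
    """Brute-force two-sided FWE p per voxel over all sign assignments."""
    n, v = mat.shape
    t_obs = stats.ttest_1samp(mat, 0.0, axis=0).statistic
    t_obs = np.nan_to_num(t_obs)
    maxima = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        flipped = np.asarray(signs)[:, None] * mat
        t = stats.ttest_1samp(flipped, 0.0, axis=0).statistic
        maxima.append(np.nanmax(np.abs(t)))
    maxima = np.asarray(maxima)
    return np.array([(maxima >= abs(t)).mean() for t in t_obs])


class TestOneSampleExhaustive:
    def test_hand_worked_single_voxel_case(self, tiny_mask):
        # lesion values (1, 2, 3): of the 8 sign assignments only the
        # identity and the full flip reach |mean| = 2, so p = 2/8
        maps = [insert(np.array([v]), tiny_mask) for v in (1.0, 2.0, 3.0)]
        smap = one_sample_permutation(maps, PermutationConfig(seed=0))
        assert smap.exhaustive
        assert smap.n_effective_perms == 8
        assert smap.p_fwe.data[0, 0, 0] == pytest.approx(0.25)

    def test_matches_brute_force_oracle_on_multivoxel_mask(self):
        rng = np.random.default_rng(3)
        mask = _flat_mask(15)
        mat = rng.standard_normal((8, 15)) + 0.6
        smap = one_sample_permutation_matrix(mat, mask, PermutationConfig(seed=0))
        assert smap.exhaustive
        expected = exhaustive_sign_flip_p(mat)
        got = smap.p_fwe.values_in_mask()
        assert np.allclose(got, expected)

    def test_all_zero_maps_p_one(self, tiny_mask):
        maps = [insert(np.zeros(1), tiny_mask) for _ in range(4)]
        smap = one_sample_permutation(maps, PermutationConfig(seed=0))
        assert np.all(smap.p_fwe.values_in_mask() == 1.0)

    def test_fewer_than_two_maps_rejected(self, tiny_mask):
        with pytest.raises(VolumeError):
            one_sample_permutation([insert(np.ones(1), tiny_mask)], PermutationConfig())

    def test_constant_nonzero_input_rejected(self):
        mask = _flat_mask(5)
        with pytest.raises(VolumeError, match="degenerate"):
            one_sample_permutation_matrix(np.full((4, 5), 2.0), mask, PermutationConfig())


class TestOneSampleMonteCarlo:
    def test_within_three_binomial_se_of_exhaustive(self):
        # n = 12 lesions on a 18-voxel mask: 2^12 = 4096 > budget, so the
        # run is Monte Carlo; the exhaustive enumeration is the oracle
        rng = np.random.default_rng(4)
        mask = _flat_mask(18)
        mat = rng.standard_normal((12, 18)) + 0.5
        cfg = PermutationConfig(n_permutations=2000, seed=9, tail_approximation=False)
        smap = one_sample_permutation_matrix(mat, mask, cfg)
        assert not smap.exhaustive
        p_exact = exhaustive_sign_flip_p(mat)
        p_mc = smap.p_fwe.values_in_mask()
        se = np.sqrt(p_exact * (1 - p_exact) / cfg.n_permutations)
        assert np.all(np.abs(p_mc - p_exact) <= 3 * se + 2 / cfg.n_permutations)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        mask = _flat_mask(10)
        mat = rng.standard_normal((13, 10))
        a = one_sample_permutation_matrix(mat, mask, PermutationConfig(seed=21))
        b = one_sample_permutation_matrix(mat, mask, PermutationConfig(seed=21))
        assert np.array_equal(a.p_fwe.data, b.p_fwe.data)

    def test_monotone_p_in_statistic(self):
        rng = np.random.default_rng(6)
        mask = _flat_mask(40)
        mat = rng.standard_normal((13, 40)) + 0.4
        smap = one_sample_permutation_matrix(mat, mask, PermutationConfig(seed=2))
        t = np.abs(smap.stat.values_in_mask())
        p = smap.p_fwe.values_in_mask()
        order = np.argsort(t)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_sign_symmetry_swaps_tails_exactly(self):
        rng = np.random.default_rng(7)
        mask = _flat_mask(25)
        mat = rng.standard_normal((13, 25)) + 0.3
        cfg = PermutationConfig(seed=3)
        pos_run = one_sample_permutation_matrix(mat, mask, cfg)
        neg_run = one_sample_permutation_matrix(-mat, mask, cfg)
        assert np.array_equal(pos_run.p_fwe_pos.data, neg_run.p_fwe_neg.data)
        assert np.array_equal(pos_run.p_fwe_neg.data, neg_run.p_fwe_pos.data)
        assert np.array_equal(pos_run.p_fwe.data, neg_run.p_fwe.data)


class TestSignificantMask:
    def test_alpha_bounds_and_strictness(self):
        rng = np.random.default_rng(8)
        mask = _flat_mask(12)
        mat = rng.standard_normal((8, 12)) + 1.0
        smap = one_sample_permutation_matrix(mat, mask, PermutationConfig(seed=0))
        assert significant_mask(smap, 1.0).n_true == mask.n_true
        # strict inequality at the boundary
        p = smap.p_fwe.values_in_mask()
        boundary = float(p.min())
        assert significant_mask(smap, boundary).n_true == int((p < boundary).sum())


class TestGPDTail:
    def test_trigger_not_met_returns_empirical(self):
        rng = np.random.default_rng(9)
        null = rng.standard_normal(2000)
        obs = float(np.median(null))
        p = gpd_tail_pvalue(obs, null, PermutationConfig())
        b = (null >= obs).sum()
        assert p == pytest.approx((1 + b) / 2001)

    def test_recovers_known_pareto_tail_probability(self):
        # geometric-mean accuracy over replicates: the fitted tail survival
        # at the true 99.9th percentile should track the true p = 0.001
        true_obs = stats.genpareto.ppf(0.999, 0.1)
        ratios = []
        for seed in range(15):
            x = stats.genpareto.rvs(0.1, size=2000, random_state=np.random.default_rng(seed))
            p = gpd_tail_pvalue(float(true_obs), x, PermutationConfig())
            ratios.append(p / 0.001)
        gm = float(np.exp(np.mean(np.log(ratios))))
        assert 0.5 <= gm <= 2.0

    def test_degenerate_tail_falls_back_with_warning(self):
        null = np.concatenate([np.linspace(0, 1, 1800), np.full(200, 5.0)])
        with pytest.warns(UserWarning, match="degenerate"):
            p = gpd_tail_pvalue(6.0, null, PermutationConfig())
        assert p == pytest.approx(1 / (1 + len(null)))

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(10)
        null = rng.standard_normal(500)
        assert gpd_tail_pvalue(-10.0, null, PermutationConfig()) <= 1.0

    def test_fit_gate_shrinks_or_rejects_bad_tail(self):
        # lattice-valued tail: no continuous GPD should pass the gate
        null = np.concatenate([np.zeros(1600), np.repeat([1.0, 2.0], 200)])
        tail = fit_gpd_tail(null, PermutationConfig())
        assert tail is None or tail.n_exceedances < 200


class TestTwoSample:
    def _design(self, n1, syndromes):
        ids, group, labels = [], [], []
        for i in range(n1):
            ids.append(f"s{i}")
            group.append("sensory")
            labels.append("")
        for name, size in syndromes.items():
            for i in range(size):
                ids.append(f"{name}{i}")
                group.append("comparison")
                labels.append(name)
        return GroupDesign(case_ids=ids, group=group, syndrome_label=labels)

    def test_equal_weight_per_syndrome(self):
        design = self._design(6, {"a": 3, "b": 5, "c": 4})
        w = design.weights
        syn = np.asarray(design.syndrome_label)
        totals = [w[syn == s].sum() for s in ("a", "b", "c")]
        assert np.allclose(totals, totals[0])
        assert np.allclose(sum(totals), 6.0)  # matches sensory total

    def test_identical_groups_t_zero_p_one(self):
        mask = _flat_mask(6)
        design = self._design(3, {"a": 3})
        x = np.tile(np.arange(6.0), (6, 1))
        smap = two_sample_permutation_matrix(
            x, mask, design, PermutationConfig(n_permutations=100, seed=0)
        )
        assert np.all(smap.stat.values_in_mask() == 0.0)
        assert np.all(smap.p_fwe.values_in_mask() == 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        mask = _flat_mask(10)
        design = self._design(4, {"a": 3, "b": 3})
        x = rng.standard_normal((10, 10))
        cfg = PermutationConfig(n_permutations=300, seed=5)
        a = two_sample_permutation_matrix(x, mask, design, cfg)
        b = two_sample_permutation_matrix(2.0 * x, mask, design, cfg)
        assert np.allclose(a.p_fwe.data, b.p_fwe.data)
        assert np.allclose(a.stat.data, b.stat.data)

    def test_unweighted_reduces_to_welch(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((9, 7))
        in_g1 = np.array([True] * 4 + [False] * 5)
        t = _weighted_welch_t(x, np.ones(9), in_g1)
        ref = stats.ttest_ind(x[:4], x[4:], equal_var=False).statistic
        assert np.allclose(t, ref)

    def test_null_rejection_rate_near_alpha(self):
        # both groups from the same null: familywise rejections ~5%
        rng = np.random.default_rng(13)
        mask = _flat_mask(30)
        design = self._design(5, {"a": 4, "b": 4, "c": 4})
        cfg = PermutationConfig(n_permutations=250, seed=17, tail_approximation=False)
        rejections = 0
        n_reps = 60
        for rep in range(n_reps):
            x = rng.standard_normal((17, 30))
            cfg_rep = PermutationConfig(
                n_permutations=250, seed=1000 + rep, tail_approximation=False
            )
            smap = two_sample_permutation_matrix(x, mask, design, cfg_rep)
            if significant_mask(smap, 0.05).n_true > 0:
                rejections += 1
        rate = rejections / n_reps
        # generous 99% binomial band around 0.05 for 60 replicates
        assert rate <= 0.18

    def test_invalid_design_rejected(self):
        with pytest.raises(VolumeError, match="syndrome_label"):
            GroupDesign(
                case_ids=["a", "b"],
                group=["sensory", "comparison"],
                syndrome_label=["", ""],
            )
        with pytest.raises(VolumeError, match="unknown group"):
            GroupDesign(case_ids=["a"], group=["patients"], syndrome_label=[""])
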