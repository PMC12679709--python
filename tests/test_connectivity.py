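"""Lesion connectivity pipeline: seed, r map, Fisher z, group T map."""

import numpy as np
import pytest

from lesionnet.connectivity import (
    Connectome,
    connectivity_maps,
    fisher_z,
    group_t_map,
    group_t_map_matrix,
    lesion_connectivity_map,
    seed_timecourse,
    subject_r_map,
)
from lesionnet.synthetic import generate_connectome, sample_lesion_cohort
from lesionnet.volumes import BinaryMask, ScalarMap, Series4D, VolumeError, VolumeGrid, insert


@pytest.fixture
def grid6():
    return VolumeGrid((6, 6, 6), np.eye(4))


def _series(grid, t, seed):
    rng = np.random.default_rng(seed)
    return Series4D(grid, rng.standard_normal(grid.shape + (t,)))


class TestSeedTimecourse:
    def test_single_voxel_lesion_returns_that_series(self, grid6):
        series = _series(grid6, 20, 0)
        lesion = np.zeros(grid6.shape, bool)
        lesion[2, 3, 4] = True
        tc = seed_timecourse(series, BinaryMask(grid6, lesion))
        assert np.array_equal(tc, series.data[2, 3, 4])

    def test_antiphase_voxels_cancel(self, grid6):
        data = np.zeros(grid6.shape + (20,))
        s = np.sin(np.arange(20.0))
        data[0, 0, 0] = s
        data[0, 0, 1] = -s
        lesion = np.zeros(grid6.shape, bool)
        lesion[0, 0, :2] = True
        tc = seed_timecourse(Series4D(grid6, data), BinaryMask(grid6, lesion))
        assert np.allclose(tc, 0.0)

    def test_mean_restricted_to_brain_mask(self, grid6):
        series = _series(grid6, 15, 1)
        lesion = np.zeros(grid6.shape, bool)
        lesion[0, 0, :6] = True
        lesion[1, 1, :4] = True  # 10 lesion voxels
        brain = np.zeros(grid6.shape, bool)
        brain[1, 1, :3] = True  # only 3 overlap the brain
        tc = seed_timecourse(series, BinaryMask(grid6, lesion), BinaryMask(grid6, brain))
        expected = series.data[1, 1, :3].mean(axis=0)
        assert np.allclose(tc, expected)

    def test_lesion_outside_brain_is_error(self, grid6):
        series = _series(grid6, 15, 2)
        lesion = np.zeros(grid6.shape, bool)
        lesion[0, 0, 0] = True
        brain = np.zeros(grid6.shape, bool)
        brain[5, 5, 5] = True
        with pytest.raises(VolumeError, match="outside"):
            seed_timecourse(series, BinaryMask(grid6, lesion), BinaryMask(grid6, brain))


class TestSubjectRMap:
    def test_self_and_anti_correlation_clamped(self, grid6):
        series = _series(grid6, 30, 3)
        series.data[1, 1, 1] = -series.data[0, 0, 0]
        brain = BinaryMask(grid6, np.ones(grid6.shape, bool))
        rmap = subject_r_map(series, series.data[0, 0, 0], brain)
        assert rmap.data[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert rmap.data[1, 1, 1] == pytest.approx(-1.0, abs=1e-6)
        assert np.all(np.abs(rmap.data) < 1.0)  # clamped, atanh stays finite

    def test_zero_variance_voxel_gets_zero(self, grid6):
        series = _series(grid6, 30, 4)
        series.data[5, 5, 5] = 7.0  # constant voxel
        brain = BinaryMask(grid6, np.ones(grid6.shape, bool))
        rmap = subject_r_map(series, series.data[0, 0, 0], brain)
        assert rmap.data[5, 5, 5] == 0.0

    def test_zero_variance_seed_flagged(self, grid6):
        series = _series(grid6, 30, 5)
        brain = BinaryMask(grid6, np.ones(grid6.shape, bool))
        with pytest.warns(UserWarning, match="zero variance"):
            rmap = subject_r_map(series, np.ones(30), brain)
        assert np.all(rmap.data == 0.0)

    def test_length_mismatch_is_error(self, grid6):
        series = _series(grid6, 30, 6)
        brain = BinaryMask(grid6, np.ones(grid6.shape, bool))
        with pytest.raises(VolumeError, match="timepoints"):
            subject_r_map(series, np.ones(29), brain)


class TestFisherZ:
    @pytest.mark.parametrize(
        "r, z",
        [(0.0, 0.0), (np.tanh(1.0), 1.0), (-np.tanh(0.5), -0.5)],
    )
    def test_known_values(self, grid6, r, z):
        data = np.full(grid6.shape, r)
        out = fisher_z(ScalarMap(grid6, data))
        assert out.data[0, 0, 0] == pytest.approx(z, abs=1e-9)


class TestGroupTMap:
    def test_closed_form_t(self, grid6):
        mask_data = np.zeros(grid6.shape, bool)
        mask_data[0, 0, 0] = True
        mask = BinaryMask(grid6, mask_data)
        maps = [insert(np.array([v]), mask) for v in (1.0, 2.0, 3.0)]
        cmap = group_t_map(maps)
        assert cmap.t_map.data[0, 0, 0] == pytest.approx(2 * np.sqrt(3))
        assert cmap.df == 2

    def test_all_zero_gives_zero_t(self, grid6):
        mask = BinaryMask(grid6, np.ones(grid6.shape, bool))
        maps = [insert(np.zeros(mask.n_true), mask) for _ in range(3)]
        cmap = group_t_map(maps)
        assert np.all(cmap.t_map.data == 0.0)

    def test_degenerate_sd_capped_with_warning(self, grid6, caplog):
        mask_data = np.zeros(grid6.shape, bool)
        mask_data[0, 0, 0] = True
        mask = BinaryMask(grid6, mask_data)
        maps = [insert(np.array([2.0]), mask) for _ in range(3)]
        with caplog.at_level("WARNING"):
            cmap = group_t_map(maps, t_cap=1e6)
        assert cmap.t_map.data[0, 0, 0] == 1e6
        assert "capped" in caplog.text

    def test_negation_equivariance(self, grid6):
        rng = np.random.default_rng(7)
        mask = BinaryMask(grid6, np.ones(grid6.shape, bool))
        mats = rng.standard_normal((4, mask.n_true))
        pos = group_t_map_matrix(mats, mask)
        neg = group_t_map_matrix(-mats, mask)
        assert np.array_equal(neg.mean_z.data, -pos.mean_z.data)
        assert np.array_equal(neg.t_map.data, -pos.t_map.data)


class TestAgainstBruteForce:
    def test_pipeline_matches_voxel_loop_oracle(self):
        """mean_z and t from the vectorized path equal a direct per-voxel loop."""
        grid = VolumeGrid((6, 6, 6), np.eye(4))
        rng = np.random.default_rng(8)
        n_subj, t_len = 4, 25
        subjects = [rng.standard_normal(grid.shape + (t_len,)) for _ in range(n_subj)]
        brain = rng.random(grid.shape) > 0.3
        lesion = np.zeros(grid.shape, bool)
        lesion[2:4, 2:4, 2] = True
        lesion &= brain
        brain_mask = BinaryMask(grid, brain)
        conn = Connectome.from_series_4d([Series4D(grid, s) for s in subjects], brain_mask)
        cmap = lesion_connectivity_map(conn, BinaryMask(grid, lesion))

        # oracle: plain python loops, no shared standardization
        clamp = 1.0 - 1e-7
        z_all = np.zeros((n_subj,) + grid.shape)
        for s, sub in enumerate(subjects):
            seed = sub[lesion].mean(axis=0)
            for idx in np.argwhere(brain):
                v = sub[tuple(idx)]
                if v.std() == 0 or seed.std() == 0:
                    r = 0.0
                else:
                    r = np.corrcoef(seed, v)[0, 1]
                z_all[(s, *idx)] = np.arctanh(np.clip(r, -clamp, clamp))
        mean_z = z_all.mean(axis=0)
        sd_z = z_all.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd_z > 0, mean_z / (sd_z / np.sqrt(n_subj)), 0.0)
        assert np.allclose(cmap.mean_z.data[brain], mean_z[brain], atol=1e-10)
        assert np.allclose(cmap.t_map.data[brain], t[brain], atol=1e-10)


class TestPlantedNetworkSignal:
    def test_remote_nodes_outshine_background(self, small_spec):
        conn = generate_connectome(small_spec)
        cases = sample_lesion_cohort(small_spec, "net1", 1.0)
        cmaps = connectivity_maps(conn, {c.case_id: c.mask for c in cases})
        target = small_spec.network("net1")
        background = conn.brain_mask.data.copy()
        for net in small_spec.networks:
            background &= ~net.union_mask.data
        for case in cases:
            t = cmaps[case.case_id].t_map.data
            remote = [
                node.data
                for node in target.node_masks
                if not (node.data & case.mask.data).any()
            ]
            assert remote, "every lesion should leave at least one remote node"
            for node in remote:
                assert t[node].mean() > t[background].mean()
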