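import numpy as np
import pytest

from plantseg3d import (PointCloud, ball_query, encode_positions,
                        relative_codes)
from plantseg3d.errors import ConfigError
from plantseg3d.geometry import NeighborhoodIndex
from plantseg3d.layers import MLP


@pytest.fixture
def thetas(rng):
    return (MLP(rng, [3, 8, 6]), MLP(rng, [3, 8, 4]))


def full_neighborhoods(n):
    idx = np.tile(np.arange(n), (n, 1))
    return NeighborhoodIndex(np.arange(n), idx, np.ones((n, n), bool))


class TestRelativeCodes:
    def test_self_offset_is_zero(self, rng):
        coords = rng.normal(size=(10, 3))
        nbr = ball_query(coords, np.arange(10), radius=0.3, k_max=4)
        rel = relative_codes(coords, nbr)
        for m in range(10):
            self_slot = list(nbr.neighbor_idx[m]).index(m)
            np.testing.assert_array_equal(rel[m, self_slot], 0.0)

    def test_translation_invariance_exact_on_dyadic_grid(self, rng):
        # dyadic coordinates + dyadic shift make float addition exact, so
        # the algebraic identity (a+t)-(b+t) = a-b holds bit for bit
        coords = rng.integers(-512, 512, size=(20, 3)) / 1024.0
        nbr = ball_query(coords, np.arange(20), radius=0.8, k_max=6)
        rel = relative_codes(coords, nbr)
        rel_t = relative_codes(coords + np.array([5.0, -3.5, 2.25]), nbr)
        np.testing.assert_array_equal(rel, rel_t)

    def test_translation_invariance_on_random_floats(self, rng):
        coords = rng.normal(size=(20, 3))
        nbr = ball_query(coords, np.arange(20), radius=0.8, k_max=6)
        rel = relative_codes(coords, nbr)
        rel_t = relative_codes(coords + np.array([5.0, -3.0, 2.0]), nbr)
        np.testing.assert_allclose(rel, rel_t, atol=1e-12)

    def test_matches_pairwise_subtraction_oracle(self, rng):
        coords = rng.normal(size=(20, 3))
        nbr = full_neighborhoods(20)
        rel = relative_codes(PointCloud(coords), nbr)
        for m in range(20):
            for k in range(20):
                np.testing.assert_allclose(rel[m, k],
                                           coords[m] - coords[k])

    def test_masked_slots_zero(self):
        coords = np.eye(3) * 9.0
        nbr = ball_query(coords, np.arange(3), radius=0.1, k_max=5)
        rel = relative_codes(coords, nbr)
        assert (rel[~nbr.valid_mask] == 0).all()


class TestEncodePositions:
    def test_neighbor_order_permutation_bitwise_invariant(self, rng, thetas):
        coords = rng.normal(size=(15, 3))
        nbr = ball_query(coords, np.arange(15), radius=1.5, k_max=8)
        pc = encode_positions(coords, nbr, *thetas)
        perm_idx = nbr.neighbor_idx.copy()
        perm_mask = nbr.valid_mask.copy()
        for m in range(15):
            k_valid = perm_mask[m].sum()
            p = rng.permutation(k_valid)
            perm_idx[m, :k_valid] = perm_idx[m, :k_valid][p]
        nbr2 = NeighborhoodIndex(nbr.centers, perm_idx, perm_mask)
        pc2 = encode_positions(coords, nbr2, *thetas)
        np.testing.assert_array_equal(pc.combined.data, pc2.combined.data)

    def test_rpc_zero_for_center_only_neighborhood(self, rng):
        # identity theta (1 linear layer, weights = I, bias 0) + max-pool of
        # the single zero offset must give exactly (0,0,0)
        theta = MLP(rng, [3, 3])
        theta.W[0].data = np.eye(3)
        theta.b[0].data = np.zeros(3)
        theta_a = MLP(rng, [3, 4])
        coords = np.eye(3) * 7.0
        nbr = ball_query(coords, np.arange(3), radius=0.1, k_max=4)
        pc = encode_positions(coords, nbr, theta, theta_a)
        np.testing.assert_array_equal(pc.rpc_features.data, np.zeros((3, 3)))

    def test_translation_moves_apc_not_rpc(self, rng, thetas):
        coords = rng.integers(-512, 512, size=(25, 3)) / 1024.0
        nbr = ball_query(coords, np.arange(25), radius=0.9, k_max=6)
        pc = encode_positions(coords, nbr, *thetas)
        pc_t = encode_positions(coords + 2.5, nbr, *thetas)
        np.testing.assert_array_equal(pc.rpc_features.data,
                                      pc_t.rpc_features.data)
        assert np.abs(pc.apc_features.data - pc_t.apc_features.data).max() > 1e-6

    def test_point_relabelling_leaves_codes_unchanged(self, rng, thetas):
        coords = rng.normal(size=(12, 3))
        nbr = ball_query(coords, np.arange(12), radius=1.0, k_max=5)
        pc = encode_positions(coords, nbr, *thetas)
        perm = rng.permutation(12)
        inv = np.argsort(perm)
        nbr_p = ball_query(coords[perm], inv[nbr.centers], radius=1.0, k_max=5)
        pc_p = encode_positions(coords[perm], nbr_p, *thetas)
        np.testing.assert_allclose(pc.combined.data, pc_p.combined.data,
                                   atol=1e-12)

    def test_combined_is_concatenation(self, rng, thetas):
        coords = rng.normal(size=(9, 3))
        nbr = ball_query(coords, np.arange(9), radius=0.7, k_max=4)
        pc = encode_positions(coords, nbr, *thetas)
        np.testing.assert_array_equal(
            pc.combined.data,
            np.hstack([pc.rpc_features.data, pc.apc_features.data]))
        assert np.isfinite(pc.combined.data).all()

    def test_uninitialized_maps_rejected(self, rng):
        coords = rng.normal(size=(5, 3))
        nbr = ball_query(coords, np.arange(5), radius=0.5, k_max=3)
        with pytest.raises(ConfigError):
            encode_positions(coords, nbr, None, None)

    def test_include_center_flag_changes_rpc_only_under_translation(
            self, rng):
        theta_r = MLP(rng, [6, 8, 5])
        theta_a = MLP(rng, [3, 8, 4])
        coords = rng.normal(size=(10, 3))
        nbr = ball_query(coords, np.arange(10), radius=0.8, k_max=4)
        pc = encode_positions(coords, nbr, theta_r, theta_a,
                              include_center_in_rpc=True)
        pc_t = encode_positions(coords + 1.0, nbr, theta_r, theta_a,
                                include_center_in_rpc=True)
        # with the centre coordinate inside the RPC tuple the branch is no
        # longer translation-invariant
        assert np.abs(pc.rpc_features.data - pc_t.rpc_features.data).max() > 1e-9
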