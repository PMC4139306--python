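"""Skin masks, Hodgkin index, electrostatic distances and their statistics."""

import math

import numpy as np
import pytest

from memesp import (
    DistanceMatrix,
    GridError,
    GridSpec,
    PotentialGrid,
    SkinMaskSpec,
    StructureModel,
    cluster_order,
    distance_autocorrelation,
    distance_stats,
    electrostatic_distance,
    hodgkin_index,
    pairwise_matrix,
    skin_mask,
)
from memesp.similarity import SkinMask


def single_atom(radius=1.5, pos=(0.0, 0.0, 0.0)):
    return StructureModel(coords=[pos], charges=[-1.0], radii=[radius],
                          names=["P1"], resnames=["ION"], resids=[1], roles={"P1": 0})


GRID = GridSpec.centered((0, 0, 0), (21, 21, 21), 0.8)


class TestSkinMask:
    def test_single_atom_brute_force(self):
        st = single_atom(radius=1.5)
        spec = SkinMaskSpec(sphere_radius=1e3)
        mask = skin_mask(st, GRID, spec)
        x, y, z = GRID.meshgrid()
        d = np.sqrt(x**2 + y**2 + z**2) - 1.5  # distance to the atom surface
        brute = (d > 2.0) & (d <= 2.0 + 3.0)
        # shell membership at voxel centers; (probe, probe+skin] interval
        assert np.array_equal(mask.values, brute)

    def test_tiny_sphere_is_empty(self):
        mask = skin_mask(single_atom(), GRID, SkinMaskSpec(sphere_radius=1e-6))
        assert mask.size == 0

    def test_defaults_probe2_skin3(self):
        spec = SkinMaskSpec()
        assert spec.probe_radius == 2.0 and spec.skin_thickness == 3.0

    def test_missing_center_tag_errors(self):
        st = single_atom()
        st.roles = {}
        with pytest.raises(Exception, match="P1"):
            skin_mask(st, GRID, SkinMaskSpec())


def masked_pair(vec_a, vec_b):
    """Two grids whose masked values are vec_a / vec_b."""
    n = len(vec_a)
    spec = GridSpec((2, 2, max(2, n)), 1.0)
    sel = np.zeros(spec.dims, dtype=bool)
    sel[0, 0, :n] = True
    va = np.zeros(spec.dims)
    vb = np.zeros(spec.dims)
    va[0, 0, :n] = vec_a
    vb[0, 0, :n] = vec_b
    return (PotentialGrid(spec, va), PotentialGrid(spec, vb),
            SkinMask(spec, sel))


class TestHodgkinIndex:
    def test_identity_and_antisymmetry(self, rng):
        a, _, mask = masked_pair(rng.normal(size=5), np.zeros(5))
        assert hodgkin_index(a, a, mask) == pytest.approx(1.0)
        neg = a.copy()
        neg.values = -neg.values
        assert hodgkin_index(a, neg, mask) == pytest.approx(-1.0)

    def test_orthogonal_vectors(self):
        a, b, mask = masked_pair([1.0, 0.0], [0.0, 1.0])
        assert hodgkin_index(a, b, mask) == pytest.approx(0.0)

    def test_error_conditions(self, rng):
        a, b, mask = masked_pair(np.zeros(3), np.zeros(3))
        with pytest.raises(GridError, match="vanish"):
            hodgkin_index(a, b, mask)
        empty = SkinMask(a.spec, np.zeros(a.spec.dims, dtype=bool))
        with pytest.raises(GridError, match="empty"):
            hodgkin_index(a, b, empty)

    def test_scaling_one_grid_matches_formula(self, rng):
        va = rng.normal(size=6)
        vb = rng.normal(size=6)
        a, b, mask = masked_pair(va, 3.0 * vb)
        direct = 2 * (va @ (3 * vb)) / (va @ va + 9 * (vb @ vb))
        assert hodgkin_index(a, b, mask) == pytest.approx(direct, rel=1e-12)
        # scaling BOTH grids leaves SI unchanged
        a2, b2, _ = masked_pair(2 * va, 6.0 * vb)
        assert hodgkin_index(a2, b2, mask) == pytest.approx(direct, rel=1e-12)


class TestElectrostaticDistance:
    @pytest.mark.parametrize("si,d", [(1.0, 0.0), (-1.0, 2.0), (0.0, math.sqrt(2))])
    def test_endpoints_and_orthogonal(self, si, d):
        assert electrostatic_distance(si) == pytest.approx(d, abs=1e-12)

    def test_monotone_decreasing_in_si(self):
        sis = np.linspace(-1, 1, 101)
        ds = [electrostatic_distance(s) for s in sis]
        assert all(x > y for x, y in zip(ds, ds[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            electrostatic_distance(1.5)


class TestPairwiseMatrix:
    def test_identical_grids_zero_matrix(self, rng):
        a, _, mask = masked_pair(rng.normal(size=4), np.zeros(4))
        m = pairwise_matrix([a, a.copy(), a.copy()], mask=mask)
        assert np.allclose(m.values, 0.0)

    def test_matches_loop_oracle(self, rng):
        vecs = rng.normal(size=(3, 5))
        grids = []
        for v in vecs:
            g, _, mask = masked_pair(v, np.zeros(5))
            grids.append(g)
        m = pairwise_matrix(grids, mask=mask)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                si = 2 * (vecs[i] @ vecs[j]) / (vecs[i] @ vecs[i] + vecs[j] @ vecs[j])
                assert m.values[i, j] == pytest.approx(math.sqrt(2 - 2 * si), rel=1e-12)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_mask_restriction_recomputes_exactly(self, rng):
        # shrinking the comparison sphere equals recomputation on the
        # smaller mask (no caching artifacts)
        st = single_atom(radius=1.0)
        g1 = PotentialGrid(GRID, rng.normal(size=GRID.dims))
        g2 = PotentialGrid(GRID, rng.normal(size=GRID.dims))
        m14 = skin_mask(st, GRID, SkinMaskSpec(probe_radius=0.5, skin_thickness=6.0,
                                               sphere_radius=7.0))
        m10 = skin_mask(st, GRID, SkinMaskSpec(probe_radius=0.5, skin_thickness=6.0,
                                               sphere_radius=5.0))
        d14 = pairwise_matrix([g1, g2], mask=m14).values[0, 1]
        d10 = pairwise_matrix([g1, g2], mask=m10).values[0, 1]
        sel = m10.values
        si = 2 * (g1.values[sel] @ g2.values[sel]) / (
            g1.values[sel] @ g1.values[sel] + g2.values[sel] @ g2.values[sel])
        assert d10 == pytest.approx(math.sqrt(2 - 2 * si), rel=1e-12)
        assert d14 != d10

    def test_per_grid_mask_intersection_policy(self, rng):
        a, b, mask = masked_pair(rng.normal(size=4), rng.normal(size=4))
        m = pairwise_matrix([a, b], masks=[mask, mask])
        shared = pairwise_matrix([a, b], mask=mask)
        assert np.allclose(m.values, shared.values)

    def test_triangle_inequality_random_triples(self, rng):
        for _ in range(200):
            vecs = rng.normal(size=(3, 8))
            grids = []
            for v in vecs:
                g, _, mask = masked_pair(v, np.zeros(8))
                grids.append(g)
            d = pairwise_matrix(grids, mask=mask).values
            assert d[0, 1] <= d[0, 2] + d[2, 1] + 1e-12
            assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12
            assert d[1, 2] <= d[1, 0] + d[0, 2] + 1e-12


class TestDistanceMatrixValidation:
    def test_invariants(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.5, 0], [0, 0]]))  # nonzero diagonal
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]))  # out of [0, 2]


class TestStatsAndACF:
    def test_stats_basics(self):
        zero = DistanceMatrix(np.zeros((3, 3)))
        s = distance_stats(zero)
        assert s["mean"] == 0.0 and s["sd"] == 0.0
        ones = np.ones((3, 3)) - np.eye(3)
        s = distance_stats(DistanceMatrix(ones))
        assert s["mean"] == 1.0 and s["sd"] == 0.0 and s["n_pairs"] == 3

    def test_stats_match_direct_computation(self, rng):
        n = 8
        v = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v[iu] = rng.uniform(0, 2, size=len(iu[0]))
        v = v + v.T
        m = DistanceMatrix(v)
        s = distance_stats(m)
        assert s["mean"] == pytest.approx(v[iu].mean())
        assert s["sd"] == pytest.approx(v[iu].std(ddof=1))
        assert s["histogram"][0].sum() == len(iu[0])

    def _iid_matrix(self, rng, n=40):
        v = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v[iu] = rng.uniform(0.4, 0.6, size=len(iu[0]))
        return DistanceMatrix(v + v.T, timestamps=list(np.arange(n) * 1.0))

    def test_iid_ensemble_has_no_lag_correlation(self, rng):
        m = self._iid_matrix(rng)
        lags, acf = distance_autocorrelation(m)
        assert acf[0] == pytest.approx(1.0)
        tri = m.upper_triangle()
        cv = tri.std() / tri.mean()
        n = len(m)
        for tau in range(1, 10):
            assert abs(acf[tau]) < 3 * cv / math.sqrt(n - tau)

    def test_drifting_ensemble_decays(self):
        # distances grow linearly with lag: close times are more similar
        n = 30
        idx = np.arange(n)
        v = np.abs(idx[:, None] - idx[None, :]) * 0.02
        m = DistanceMatrix(v, timestamps=list(idx * 0.5))
        _, acf = distance_autocorrelation(m)
        assert acf[1] > acf[5]

    def test_alternating_ensemble_alternates_sign(self):
        # two grids A/B alternating: D=0 at even lags, d at odd lags
        n = 12
        idx = np.arange(n)
        v = np.where((np.abs(idx[:, None] - idx[None, :]) % 2) == 1, 0.8, 0.0)
        np.fill_diagonal(v, 0.0)
        m = DistanceMatrix(v)
        _, acf = distance_autocorrelation(m)
        signs = np.sign(acf[:6])
        assert np.array_equal(signs, [1, -1, 1, -1, 1, -1])

    def test_zero_variance_errors(self):
        m = DistanceMatrix(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="undefined"):
            distance_autocorrelation(m)

    def test_nonuniform_timestamps_rejected(self, rng):
        m = self._iid_matrix(rng, n=5)
        m.timestamps = [0.0, 1.0, 2.0, 4.0, 5.0]
        with pytest.raises(ValueError, match="uniform"):
            distance_autocorrelation(m)

    def test_cluster_order_is_permutation(self, rng):
        m = self._iid_matrix(rng, n=9)
        order = cluster_order(m)
        assert sorted(order) == list(range(9))
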