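import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from efgmep import (
    BasisKind,
    WeightKind,
    influence_radii,
    make_regular_grid,
    mls_shape,
    neighbors,
    weight,
)
from efgmep.errors import InvalidArgumentError, SingularMomentMatrixError
from efgmep.mls import mls_shape_many

from oracles import brute_phi


class TestWeightFunctions:
    @pytest.mark.parametrize(
        "kind,r,expect",
        [
            (WeightKind.CUBIC, 0.0, 2.0 / 3.0),
            (WeightKind.CUBIC, 0.5, 1.0 / 6.0),
            (WeightKind.QUARTIC, 0.0, 1.0),
            (WeightKind.QUARTIC, 1.0, 0.0),
            (WeightKind.CUBIC, 1.2, 0.0),
        ],
    )
    def test_printed_values(self, kind, r, expect):
        w, _ = weight(kind, r)
        assert w == pytest.approx(expect, abs=1e-14)

    def test_compact_support_kills_derivative(self):
        _, dw = weight(WeightKind.CUBIC, 1.2)
        assert dw == 0.0

    @pytest.mark.parametrize("kind", list(WeightKind))
    @pytest.mark.parametrize("seam", [0.5, 1.0])
    def test_continuity_at_seams(self, kind, seam):
        eps = 1e-8
        w_lo, _ = weight(kind, seam - eps)
        w_hi, _ = weight(kind, seam + eps)
        max_slope = max(abs(weight(kind, r)[1]) for r in np.linspace(0, 1, 201))
        assert abs(w_lo - w_hi) <= 3 * eps * max_slope

    @given(st.floats(min_value=0.0, max_value=0.999))
    def test_derivative_matches_finite_difference(self, r):
        eps = 1e-7
        for kind in WeightKind:
            w_p, _ = weight(kind, r + eps)
            w_m, _ = weight(kind, max(r - eps, 0.0))
            _, dw = weight(kind, r)
            span = (r + eps) - max(r - eps, 0.0)
            # skip across-seam stencils: one-sided truncation error is O(eps)
            if not (r - eps < 0.5 < r + eps or r - eps < 1.0 < r + eps):
                assert (w_p - w_m) / span == pytest.approx(dw, abs=1e-5)

    def test_negative_r_rejected(self):
        with pytest.raises(InvalidArgumentError):
            weight(WeightKind.CUBIC, -0.1)


class TestInfluenceRadii:
    def test_regular_grid_uniform(self, grid1d_cloud):
        cloud, _ = grid1d_cloud
        radii = influence_radii(cloud, 2.0)
        assert np.allclose(radii.c, 1.0)
        assert np.allclose(radii.d_m, 2.0)

    def test_two_nodes(self):
        from efgmep import NodeCloud

        cloud = NodeCloud(np.array([[0.0], [3.0]]))
        radii = influence_radii(cloud, 1.5)
        assert np.allclose(radii.d_m, 4.5)

    def test_nonpositive_d_max_rejected(self, grid1d_cloud):
        with pytest.raises(InvalidArgumentError):
            influence_radii(grid1d_cloud[0], 0.0)


class TestNeighbors:
    def test_self_inclusion_and_interior_count(self, grid1d_cloud):
        cloud, _ = grid1d_cloud
        radii = influence_radii(cloud, 2.0)
        idx = neighbors([5.0], cloud, radii)
        # node 5 plus nodes 4 and 6 (distance 1 < 2); 3 and 7 are at exactly
        # 2 = d_m, excluded by the strict inequality
        assert idx.tolist() == [4, 5, 6]

    def test_far_point_is_empty(self, grid1d_cloud):
        cloud, _ = grid1d_cloud
        radii = influence_radii(cloud, 2.0)
        assert neighbors([100.0], cloud, radii).size == 0

    def test_ascending_order(self, irregular2d_cloud):
        cloud, _ = irregular2d_cloud
        radii = influence_radii(cloud, 2.5)
        idx = neighbors([0.5, 0.5], cloud, radii)
        assert np.all(np.diff(idx) > 0)


class TestShapeFunctions:
    def test_symmetric_node_matches_direct_least_squares(self):
        """MLS shape functions are non-interpolatory: at the middle of three
        equispaced nodes the weighted linear fit distributes weight as
        (w(1/2), w(0), w(1/2)) normalized — (1/6, 2/3, 1/6) for the cubic
        spline — which the brute-force oracle confirms."""
        cloud, _ = make_regular_grid([(0.0, 2.0)], [3])
        radii = influence_radii(cloud, 2.0)
        for kind in WeightKind:
            se = mls_shape([1.0], cloud, radii, kind, BasisKind.LINEAR)
            idx, phi_ref = brute_phi(
                [1.0], cloud.positions, radii.d_m, kind, BasisKind.LINEAR
            )
            assert np.array_equal(se.node_indices, idx)
            assert np.allclose(se.phi, phi_ref, atol=1e-10)
            if kind == WeightKind.CUBIC:
                assert np.allclose(se.phi, [1 / 6, 2 / 3, 1 / 6], atol=1e-12)
            assert se.phi.sum() == pytest.approx(1.0, abs=1e-12)
            assert se.phi @ cloud.positions[idx, 0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kind", list(WeightKind))
    @pytest.mark.parametrize("basis", list(BasisKind))
    def test_partition_of_unity_and_reproduction(self, irregular2d_cloud, rng, kind, basis):
        cloud, _ = irregular2d_cloud
        radii = influence_radii(cloud, 2.5)
        pts = rng.uniform(0.15, 0.85, size=(200, 2))
        batches, singles = mls_shape_many(pts, cloud, radii, kind, basis)
        evs = [(b.node_indices[k], b.phi[k], b.dphi[k], b.points[k])
               for b in batches for k in range(b.point_ids.size)]
        evs += [(s.node_indices, s.phi, s.dphi, s.point) for _, s in singles]
        assert len(evs) == 200
        for idx, phi, dphi, pt in evs:
            assert phi.sum() == pytest.approx(1.0, abs=1e-10)
            scale = max(1.0, float(np.abs(dphi).max()))
            assert np.allclose(dphi.sum(axis=0), 0.0, atol=1e-8 * scale)
            xy = cloud.positions[idx]
            assert np.allclose(phi @ xy, pt, atol=1e-9)
            if basis == BasisKind.QUADRATIC:
                assert phi @ (xy[:, 0] ** 2) == pytest.approx(pt[0] ** 2, abs=1e-8)
                assert phi @ (xy[:, 0] * xy[:, 1]) == pytest.approx(
                    pt[0] * pt[1], abs=1e-8
                )

    def test_matches_brute_force_oracle(self, irregular2d_cloud, rng):
        cloud, _ = irregular2d_cloud
        radii = influence_radii(cloud, 2.2)
        for _ in range(100):
            pt = rng.uniform(0.1, 0.9, size=2)
            kind = list(WeightKind)[int(rng.integers(2))]
            se = mls_shape(pt, cloud, radii, kind, BasisKind.LINEAR)
            idx, phi = brute_phi(pt, cloud.positions, radii.d_m, kind, BasisKind.LINEAR)
            assert np.array_equal(se.node_indices, idx)
            assert np.allclose(se.phi, phi, atol=1e-9)

    @pytest.mark.parametrize("kind", list(WeightKind))
    def test_derivatives_match_finite_differences(self, irregular2d_cloud, rng, kind):
        cloud, _ = irregular2d_cloud
        radii = influence_radii(cloud, 2.2)
        step = 1e-6 * np.min(radii.c)
        for _ in range(20):
            pt = rng.uniform(0.15, 0.85, size=2)
            se = mls_shape(pt, cloud, radii, kind)
            for ax in range(2):
                e = np.zeros(2)
                e[ax] = step
                sp = mls_shape(pt + e, cloud, radii, kind)
                sm = mls_shape(pt - e, cloud, radii, kind)
                if not np.array_equal(sp.node_indices, sm.node_indices):
                    continue  # support boundary crossed inside the stencil
                fd = (sp.phi - sm.phi) / (2 * step)
                scale = max(np.max(np.abs(fd)), 1.0)
                assert np.allclose(se.dphi[:, ax], fd, atol=1e-5 * scale)

    def test_convergence_of_quadratic_field_interpolation(self):
        """Nodal x^2 interpolated with a linear basis: error drops at
        second order as the grid is refined."""
        errs = []
        hs = [0.2, 0.1, 0.05]
        for h in hs:
            n = int(round(2.0 / h)) + 1
            cloud, _ = make_regular_grid([(-1.0, 1.0)], [n])
            radii = influence_radii(cloud, 2.0)
            u = cloud.positions[:, 0] ** 2
            pts = np.linspace(-0.8, 0.8, 41)
            err = 0.0
            for p in pts:
                se = mls_shape([p], cloud, radii)
                err = max(err, abs(se.phi @ u[se.node_indices] - p * p))
            errs.append(err)
        order = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert order >= 2.0 - 0.2

    def test_singular_error_reports_context(self):
        # 3 collinear nodes cannot support a 2D linear basis anywhere
        from efgmep import NodeCloud

        cloud = NodeCloud(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
        radii = influence_radii(cloud, 2.0)
        with pytest.raises(SingularMomentMatrixError) as exc:
            mls_shape([1.0, 0.1], cloud, radii)
        assert exc.value.n_neighbors >= 0

    def test_batch_equals_single_path(self, irregular2d_cloud, rng):
        cloud, _ = irregular2d_cloud
        radii = influence_radii(cloud, 2.0)
        pts = rng.uniform(0.2, 0.8, size=(50, 2))
        batches, singles = mls_shape_many(pts, cloud, radii)
        for b in batches:
            for k in range(b.point_ids.size):
                se = mls_shape(pts[b.point_ids[k]], cloud, radii)
                assert np.array_equal(se.node_indices, b.node_indices[k])
                assert np.allclose(se.phi, b.phi[k], atol=1e-13)
                assert np.allclose(se.dphi, b.dphi[k], atol=1e-13)

    def test_min_neighbors_floor_grows_support(self, irregular2d_cloud):
        cloud, _ = irregular2d_cloud
        radii = influence_radii(cloud, 1.5)
        se_plain = mls_shape([0.5, 0.5], cloud, radii)
        need = se_plain.node_indices.size + 3
        se_floor = mls_shape([0.5, 0.5], cloud, radii, min_neighbors=need)
        assert se_floor.node_indices.size >= need
        assert se_floor.phi.sum() == pytest.approx(1.0, abs=1e-10)
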