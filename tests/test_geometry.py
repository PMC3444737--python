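import numpy as np
import pytest

from efgmep import (
    Domain,
    FiberField,
    NodeCloud,
    assign_split_fibers,
    assign_uniform_fibers,
    make_irregular_cloud,
    make_regular_grid,
    make_ventricle_shell,
)
from efgmep.errors import CapacityError, InvalidArgumentError
from efgmep.geometry import read_node_file, write_node_file


class TestRegularGrid:
    @pytest.mark.parametrize(
        "bounds,counts,n_expect,spacing",
        [
            ([(0, 60)] * 3, [10, 10, 10], 1000, 60 / 9),
            ([(0, 20)] * 2, [21, 21], 441, 1.0),
            ([(0, 1)], [2], 2, 1.0),
        ],
    )
    def test_counts_and_spacing(self, bounds, counts, n_expect, spacing):
        cloud, dom = make_regular_grid(bounds, counts)
        assert cloud.n_nodes == n_expect
        axis0 = np.unique(cloud.positions[:, 0])
        assert np.allclose(np.diff(axis0), spacing)
        assert np.all(dom.inside(cloud.positions))

    def test_two_point_lattice(self):
        cloud, _ = make_regular_grid([(0, 1)], [2])
        assert np.allclose(np.sort(cloud.positions[:, 0]), [0.0, 1.0])

    @pytest.mark.parametrize(
        "bounds,counts",
        [([(0, 0)], [5]), ([(0, 1)], [1]), ([(1, 0)], [3])],
    )
    def test_invalid_arguments(self, bounds, counts):
        with pytest.raises(InvalidArgumentError):
            make_regular_grid(bounds, counts)


class TestIrregularCloud:
    def test_count_spacing_and_determinism(self):
        dom = Domain("unit_cube", [(0, 1)] * 3)
        c1 = make_irregular_cloud(dom, 200, min_spacing=0.05, seed=11)
        c2 = make_irregular_cloud(dom, 200, min_spacing=0.05, seed=11)
        assert c1.n_nodes == 200
        assert np.array_equal(c1.positions, c2.positions)
        assert np.all(dom.inside(c1.positions))
        d, _ = c1.kdtree.query(c1.positions, k=2)
        assert np.min(d[:, 1]) >= 0.05

    def test_single_node(self):
        dom = Domain("square", [(0, 1)] * 2)
        c = make_irregular_cloud(dom, 1, min_spacing=0.1, seed=0)
        assert c.n_nodes == 1 and dom.inside(c.positions)[0]

    def test_capacity_error_reports_placed(self):
        dom = Domain("tiny", [(0, 1)] * 2)
        with pytest.raises(CapacityError) as exc:
            make_irregular_cloud(dom, 1000, min_spacing=0.2, seed=0)
        assert 0 < exc.value.placed < 1000

    def test_paper_scale_cloud(self):
        dom = Domain("cube60", [(0, 60)] * 3)
        c = make_irregular_cloud(dom, 1106, min_spacing=60 / 13.0, seed=42)
        assert c.n_nodes == 1106


class TestVentricleShell:
    def test_node_count_fibers_containment(self):
        cloud, fibers, dom = make_ventricle_shell(n=500, seed=1)
        assert cloud.n_nodes == 500
        assert fibers.vectors.shape == (500, 3)
        assert np.allclose(np.linalg.norm(fibers.vectors, axis=1), 1.0, atol=1e-12)
        assert np.all(dom.inside(cloud.positions))

    def test_zero_helix_gives_circumferential_fibers(self):
        cloud, fibers, _ = make_ventricle_shell(
            n=300, helix_angle_range=(0.0, 0.0), seed=2
        )
        # circumferential: no z-component, orthogonal to the radial direction
        off_axis = np.linalg.norm(cloud.positions[:, :2], axis=1) > 3.0
        assert np.max(np.abs(fibers.vectors[off_axis, 2])) < 0.15
        radial = cloud.positions[:, :2] / np.linalg.norm(
            cloud.positions[:, :2], axis=1, keepdims=True
        )
        dots = np.abs(np.sum(fibers.vectors[:, :2] * radial, axis=1))
        assert np.median(dots[off_axis]) < 0.2

    def test_endo_inside_epi_required(self):
        with pytest.raises(InvalidArgumentError):
            make_ventricle_shell(epi_semi_axes=(20, 20, 30), endo_semi_axes=(25, 18, 25))


class TestFiberAssignment:
    def test_uniform_paper_direction(self, grid2d_cloud):
        cloud, _ = make_regular_grid([(0, 60)] * 3, [4, 4, 4])
        f = assign_uniform_fibers(cloud, (0.57735, 0.57735, -0.57735))
        expect = np.array([0.57735, 0.57735, -0.57735])
        expect /= np.linalg.norm(expect)
        assert np.allclose(f.vectors, expect, atol=1e-9)

    def test_normalization(self):
        cloud, _ = make_regular_grid([(0, 1)] * 3, [2, 2, 2])
        f = assign_uniform_fibers(cloud, (2, 0, 0))
        assert np.allclose(f.vectors, [1.0, 0.0, 0.0])

    def test_split_field(self):
        cloud, _ = make_regular_grid([(0, 60)] * 3, [5, 5, 5])
        f = assign_split_fibers(cloud, 0, 30.0, (1, 0, 0), (0, 1, 0))
        left = cloud.positions[:, 0] < 30.0
        assert np.allclose(f.vectors[left], [1, 0, 0])
        assert np.allclose(f.vectors[~left], [0, 1, 0])

    def test_zero_direction_rejected(self):
        cloud, _ = make_regular_grid([(0, 1)] * 2, [2, 2])
        with pytest.raises(InvalidArgumentError):
            assign_uniform_fibers(cloud, (0, 0, 0))


class TestNodeFileRoundTrip:
    def test_with_fibers(self, tmp_path):
        cloud, fibers, _ = make_ventricle_shell(n=50, seed=4)
        path = tmp_path / "nodes.txt"
        write_node_file(path, cloud, fibers)
        cloud2, fibers2 = read_node_file(path)
        assert np.allclose(cloud2.positions, cloud.positions)
        assert np.allclose(fibers2.vectors, fibers.vectors)

    def test_without_fibers(self, tmp_path):
        cloud, _ = make_regular_grid([(0, 5)] * 2, [3, 4])
        path = tmp_path / "nodes.txt"
        write_node_file(path, cloud)
        cloud2, fibers2 = read_node_file(path)
        assert fibers2 is None
        assert np.allclose(cloud2.positions, cloud.positions)


def test_coincident_nodes_rejected_by_radii():
    from efgmep import influence_radii
    from efgmep.errors import DegenerateGeometryError

    cloud = NodeCloud(np.array([[0.0], [0.0], [1.0]]))
    with pytest.raises(DegenerateGeometryError):
        influence_radii(cloud, 2.0)


def test_fiber_field_requires_unit_vectors():
    with pytest.raises(InvalidArgumentError):
        FiberField(vectors=np.array([[1.0, 1.0, 0.0]]))
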