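"""Network parameters: oracles, symmetry laws and scale laws."""

import numpy as np
import pytest

from myocap3d import (
    CapillaryGraph,
    FibreModel,
    FibreSection,
    UndefinedMetricError,
    anisotropy,
    branching_density,
    compute_morphometry,
    fibre_geometry,
    fibre_normalised_densities,
    length_density_LVm,
    mean_capillary_length,
    tortuosity,
    total_length,
)
from myocap3d.capmetrics import orientation_tensor


def line_graph(points_list):
    g = CapillaryGraph()
    for pts in points_list:
        pts = np.asarray(pts, float)
        a = g.add_node(pts[0])
        b = g.add_node(pts[-1])
        g.add_edge(a, b, pts)
    return g


class TestLengthAndDensities:
    def test_single_segment_length(self):
        g = line_graph([[[0, 0, 0], [5, 0, 0]]])
        assert total_length(g) == pytest.approx(5.0)

    def test_additive_over_disjoint_edges(self):
        g = line_graph([[[0, 0, 0], [7, 0, 0]], [[0, 10, 0], [0, 13, 0]]])
        assert total_length(g) == pytest.approx(10.0)

    def test_empty_graph_is_zero(self):
        assert total_length(CapillaryGraph()) == 0.0

    def test_lvm_arithmetic_oracle(self):
        # 9000 µm in a 387.5² × 100 µm³ field
        g = line_graph([[[0, 0, 0], [9000, 0, 0]]])
        vol = 387.5**2 * 100
        assert length_density_LVm(g, vol) == pytest.approx(9000 / 1.5015625e7)
        assert length_density_LVm(g, vol) == pytest.approx(5.99e-4, rel=1e-3)

    def test_volume_homogeneity(self):
        g = line_graph([[[0, 0, 0], [100, 0, 0]]])
        assert length_density_LVm(g, 2000.0) == pytest.approx(length_density_LVm(g, 1000.0) / 2)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            length_density_LVm(CapillaryGraph(), 0.0)


class TestBranchingDensity:
    def test_y_graph_one_branch_point(self):
        g = CapillaryGraph()
        c = g.add_node([0, 0, 0])
        for tip in ([10, 0, 0], [0, 10, 0], [-5, -5, 0]):
            t = g.add_node(tip)
            g.add_edge(c, t, np.array([[0, 0, 0], tip], float))
        assert branching_density(g, 1.0) == pytest.approx(1.0)

    def test_simple_path_has_none(self):
        g = line_graph([[[0, 0, 0], [10, 0, 0], [20, 5, 0]]])
        assert branching_density(g, 1.0) == 0.0


class TestMeanCap:
    def test_direct_substitution(self):
        assert mean_capillary_length(3.0, 2.0) == pytest.approx(1.0)

    def test_table_scale_arithmetic(self):
        assert mean_capillary_length(6e-4, 1.37e-6) == pytest.approx(291.97, rel=1e-4)

    def test_homogeneity_in_volume(self):
        assert mean_capillary_length(6.0, 1.4) == pytest.approx(mean_capillary_length(60.0, 14.0))

    def test_zero_branching_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            mean_capillary_length(1.0, 0.0)

    def test_field_totals_equal_density_ratio(self):
        # MeanCap from (LV, NV) of the same field == (2/3)·L/B regardless of volume
        g = CapillaryGraph()
        c = g.add_node([0, 0, 0])
        for tip in ([30, 0, 0], [0, 40, 0], [0, 0, 50]):
            t = g.add_node(tip)
            g.add_edge(c, t, np.array([[0, 0, 0], tip], float))
        for vol in (1.0, 123.4, 9.9e6):
            lv, nv = length_density_LVm(g, vol), branching_density(g, vol)
            assert mean_capillary_length(lv, nv) == pytest.approx((2 / 3) * 120.0 / 1.0)


class TestTortuosity:
    def test_straight_polyline_zero(self):
        g = line_graph([[[0, 0, 0], [50, 0, 0], [100, 0, 0]]])
        assert tortuosity(g) == pytest.approx(0.0, abs=1e-12)

    def test_single_right_angle(self):
        g = line_graph([[[0, 0, 0], [50, 0, 0], [50, 50, 0]]])
        assert tortuosity(g) == pytest.approx((np.pi / 2) / 100.0)
        assert tortuosity(g) == pytest.approx(15.71e-3, rel=1e-3)

    def test_zigzag_matches_brute_force_angle_sum(self, rng):
        # planar zigzag with n identical turns of angle theta
        theta, seg, n = 0.4, 5.0, 12
        pts = [np.zeros(3)]
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(n + 1):
            s = 1 if i % 2 == 0 else -1
            c, sn = np.cos(s * theta / 2), np.sin(s * theta / 2)
            d = np.array([c * direction[0] - sn * direction[1], sn * direction[0] + c * direction[1], 0])
            # alternate headings so each interior vertex turns by exactly theta
            pts.append(pts[-1] + seg * d)
        pts = np.asarray(pts)
        g = line_graph([pts])
        brute = 0.0
        for i in range(1, len(pts) - 1):
            u = pts[i] - pts[i - 1]
            v = pts[i + 1] - pts[i]
            cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            brute += np.arccos(np.clip(cosang, -1, 1))
        assert tortuosity(g) == pytest.approx(brute / total_length(g), rel=1e-12)
        assert tortuosity(g) == pytest.approx(n * theta / (seg * (n + 1)), rel=1e-9)

    def test_zero_length_graph_undefined(self):
        with pytest.raises(UndefinedMetricError):
            tortuosity(CapillaryGraph())

    def test_rotation_invariance(self, rng):
        pts = np.cumsum(rng.normal(size=(30, 3)), axis=0) * 5
        g = line_graph([pts])
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        g_rot = g.transform(lambda p: p @ q.T)
        assert tortuosity(g_rot) == pytest.approx(tortuosity(g), rel=1e-9)


class TestAnisotropy:
    def test_orthogonal_triad_is_isotropic(self):
        g = line_graph(
            [[[0, 0, 0], [10, 0, 0]], [[0, 0, 0], [0, 10, 0]], [[0, 0, 0], [0, 0, 10]]]
        )
        assert anisotropy(g) == pytest.approx(1.0)

    def test_parallel_segments_flagged_infinite(self):
        g = line_graph([[[0, 0, 0], [0, 0, 10]], [[5, 0, 0], [5, 0, 10]]])
        with pytest.warns(UserWarning, match="aligned"):
            assert anisotropy(g) == np.inf

    def test_monte_carlo_matches_explicit_tensor_sum(self, rng):
        # 10⁴ random segments: library value vs independent explicit summation
        n = 10_000
        t = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        w = np.exp(2.0 * t**2)  # axially concentrated weights
        keep = rng.uniform(0, np.exp(2.0), n) < w
        t, phi = t[keep], phi[keep]
        s = np.sqrt(1 - t**2)
        dirs = np.column_stack([s * np.cos(phi), s * np.sin(phi), t])
        lengths = rng.uniform(3, 7, len(dirs))
        g = CapillaryGraph()
        for d, ln in zip(dirs, lengths):
            a = g.add_node([0, 0, 0])
            b = g.add_node(d * ln)
            g.add_edge(a, b, np.vstack([[0, 0, 0], d * ln]))
        T = np.zeros((3, 3))
        for d, ln in zip(dirs, lengths):
            T += ln * np.outer(d, d)
        T /= lengths.sum()
        lam = np.sort(np.linalg.eigvalsh(T))[::-1]
        expected = lam[0] / (0.5 * (lam[1] + lam[2]))
        assert anisotropy(g) == pytest.approx(expected, rel=1e-9)
        assert np.allclose(orientation_tensor(g), T)

    def test_rotation_invariance(self, rng):
        pts = np.cumsum(rng.normal(size=(40, 3)), axis=0) * 4
        g = line_graph([pts])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        g_rot = g.transform(lambda p: p @ q.T)
        assert anisotropy(g_rot) == pytest.approx(anisotropy(g), rel=1e-8)

    def test_alternative_definitions_ordering(self, rng):
        pts = np.cumsum(rng.normal(size=(60, 3)) + [0, 0, 1.0], axis=0)
        g = line_graph([pts])
        a_mean = anisotropy(g, "max_over_mean")
        a_min = anisotropy(g, "max_over_min")
        a_mid = anisotropy(g, "max_over_mid")
        assert a_mid <= a_mean <= a_min


class TestScaleLaws:
    def test_metric_scaling_exponents(self, rng):
        pts = np.cumsum(rng.normal(size=(50, 3)), axis=0) * 5 + 100
        g = line_graph([pts])
        s = 3.0
        gs = g.transform(lambda p: p * s)
        vol = 1e6
        assert tortuosity(gs) == pytest.approx(tortuosity(g) / s, rel=1e-9)
        assert anisotropy(gs) == pytest.approx(anisotropy(g), rel=1e-9)
        assert length_density_LVm(gs, vol * s**3) == pytest.approx(
            length_density_LVm(g, vol) / s**2, rel=1e-9
        )
        assert branching_density(gs, vol * s**3) == pytest.approx(
            branching_density(g, vol) / s**3, rel=1e-9
        )


def cylinder_fibre(radius, z_planes, n_pts=200):
    theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    circle = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    return FibreSection(1, np.asarray(z_planes, float), [circle.copy() for _ in z_planes])


class TestFibreGeometry:
    def test_cylinder_volume_surface_diameter(self):
        f = cylinder_fibre(15.0, [0, 33.3, 66.7, 100.0])
        d, s, v = fibre_geometry(f.contours, f.plane_z)
        assert v == pytest.approx(np.pi * 15**2 * 100, rel=5e-3)
        assert s == pytest.approx(np.pi * 30 * 100, rel=5e-3)
        assert d == pytest.approx(30.0, rel=5e-3)

    def test_conical_frustum_volume(self):
        # linear taper radius 20 -> 10 over 90 µm, fine plane sampling
        zs = np.linspace(0, 90, 31)
        contours = []
        for z in zs:
            r = 20 - (10 / 90) * z
            theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
            contours.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        _, _, v = fibre_geometry(contours, zs)
        frustum = np.pi * 90 / 3 * (20**2 + 20 * 10 + 10**2)
        assert v == pytest.approx(frustum, rel=5e-3)

    def test_square_contour_min_feret_is_side(self):
        sq = np.array([[0, 0], [8, 0], [8, 8], [0, 8]], float)
        d, _, _ = fibre_geometry([sq, sq], [0.0, 10.0])
        assert d == pytest.approx(8.0)

    def test_self_intersecting_contour_names_fibre(self):
        bow = np.array([[0, 0], [4, 4], [4, 0], [0, 4]], float)
        with pytest.raises(Exception, match="fibre 7"):
            fibre_geometry([bow, bow], [0.0, 10.0], fibre_id=7)


class TestFibreNormalisedDensities:
    def test_ll_oracle(self):
        g = line_graph([[[0, 0, 0], [350, 0, 0]]])
        f = FibreModel([cylinder_fibre(15.0, [0, 50, 100])], z_bounds=(0.0, 100.0))
        LL, LSf, LVf = fibre_normalised_densities(g, f)
        assert LL == pytest.approx(3.5)
        assert LSf == pytest.approx(350 / (np.pi * 30 * 100), rel=5e-3)
        assert LVf == pytest.approx(350 / (np.pi * 15**2 * 100), rel=5e-3)

    def test_compute_morphometry_bundles_consistently(self, dia_field_run):
        truth, measured = dia_field_run
        # MeanCap identity on the measured field: ratio of its own totals
        assert measured.MeanCap == pytest.approx(
            (2 / 3) * measured.LVm / measured.Br_dens, rel=1e-12
        )
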