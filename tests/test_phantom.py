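"""Phantom generation: grids, rasterisation, perturbations, cohorts."""
import dataclasses

import numpy as np
import pytest

from contourdose import (CohortSpec, PerturbationSpec, StructureTemplate,
                         make_grid, perturb, rasterize_sphere, rasterize_tube,
                         simulate_cohort, simulate_subject)
from contourdose.errors import EmptyStructureError
from contourdose.phantom import boundary_voxels


class TestGrid:
    def test_voxel_centers_and_volume(self):
        g = make_grid((10, 10, 10), (1, 1, 1))
        assert g.n_voxels == 1000
        assert g.indices_to_mm(np.array([[0, 0, 0]]))[0] == pytest.approx([0, 0, 0])
        g2 = make_grid((4, 4, 2), (1, 1, 3))
        assert g2.voxel_volume_mm3 == pytest.approx(3.0)

    def test_index_coordinate_roundtrip(self):
        g = make_grid((5, 6, 7), (1.5, 2.0, 2.5), origin=(-3, 1, 0))
        idx = np.array([[0, 0, 0], [4, 5, 6], [2, 3, 1]])
        mm = g.indices_to_mm(idx)
        back = (mm - np.asarray(g.origin)) / np.asarray(g.spacing)
        np.testing.assert_allclose(back, idx)

    @pytest.mark.parametrize("shape,spacing", [
        ((0, 5, 5), (1, 1, 1)), ((5, 5, 5), (0, 1, 1)), ((5, -1, 5), (1, 1, 1)),
    ])
    def test_invalid_grid_rejected(self, shape, spacing):
        with pytest.raises(ValueError):
            make_grid(shape, spacing)


class TestRasterizeSphere:
    def test_tiny_sphere_occupies_single_voxel(self, unit_grid):
        m = rasterize_sphere(unit_grid, (5, 5, 5), 0.4, "s")
        assert m.count == 1
        assert m.voxels[5, 5, 5]

    def test_volume_matches_analytic_within_5pct(self, grid21):
        # Voxel-centre counting converges on the analytic sphere volume.
        m = rasterize_sphere(grid21, (10, 10, 10), 10.0, "s")
        analytic = 4.0 / 3.0 * np.pi * 10.0 ** 3
        assert abs(m.volume_mm3 - analytic) / analytic < 0.05

    def test_sphere_missing_all_centers_is_error(self, unit_grid):
        with pytest.raises(EmptyStructureError):
            rasterize_sphere(unit_grid, (4.5, 4.5, 4.5), 0.1, "s")

    def test_center_outside_extent_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            rasterize_sphere(unit_grid, (50, 5, 5), 2.0, "s")


class TestRasterizeTube:
    def test_thin_axial_tube_is_a_column(self, grid21):
        m = rasterize_tube(grid21, (0, 0, 1), (10, 10, 10), 0.4, 10.0, "t")
        assert m.count == 11  # centres at z = 5..15 inclusive
        assert m.voxels[10, 10, 5:16].all()

    def test_zero_length_equals_sphere(self, grid21):
        tube = rasterize_tube(grid21, (0, 0, 1), (10, 10, 10), 3.0, 0.0, "t")
        sphere = rasterize_sphere(grid21, (10, 10, 10), 3.0, "s")
        np.testing.assert_array_equal(tube.voxels, sphere.voxels)

    def test_oblique_tube_volume_near_cylinder(self):
        g = make_grid((40, 40, 40), (1, 1, 1))
        u = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        r, length = 5.0, 20.0
        m = rasterize_tube(g, u, (19.5, 19.5, 19.5), r, length, "t")
        # Capsule = cylinder + sphere caps.
        analytic = np.pi * r ** 2 * length + 4.0 / 3.0 * np.pi * r ** 3
        assert abs(m.volume_mm3 - analytic) / analytic < 0.10


class TestPerturb:
    def test_translate_is_a_rigid_shift(self, grid21):
        m = rasterize_sphere(grid21, (10, 10, 10), 4.0, "s")
        out = perturb(m, PerturbationSpec("translate", 3.0, axis=(1, 0, 0)))
        assert out.count == m.count
        np.testing.assert_allclose(out.centroid_mm() - m.centroid_mm(), [3, 0, 0])

    @pytest.mark.parametrize("kind,kwargs", [
        ("translate", {"axis": None}), ("dilate", {}), ("erode", {}),
        ("truncate_axial", {}), ("surface_noise", {"seed": 3}),
    ])
    def test_zero_magnitude_is_identity(self, grid21, kind, kwargs):
        m = rasterize_sphere(grid21, (10, 10, 10), 5.0, "s")
        out = perturb(m, PerturbationSpec(kind, 0.0, **kwargs))
        np.testing.assert_array_equal(out.voxels, m.voxels)

    def test_truncate_removes_top_of_extent(self, grid21):
        tube = rasterize_tube(grid21, (0, 0, 1), (10, 10, 10), 0.4, 10.0, "t")
        out = perturb(tube, PerturbationSpec("truncate_axial", 3.0))
        assert out.count == 8  # z centres 5..12 survive; 13,14,15 removed

    def test_dilate_monotone_erode_antitone(self, grid21):
        m = rasterize_sphere(grid21, (10, 10, 10), 5.0, "s")
        big = perturb(m, PerturbationSpec("dilate", 2.0))
        small = perturb(m, PerturbationSpec("erode", 2.0))
        assert (big.voxels | m.voxels).sum() == big.count  # superset
        assert (small.voxels & m.voxels).sum() == small.count  # subset
        assert small.count < m.count < big.count

    def test_erode_to_nothing_is_error(self, grid21):
        m = rasterize_sphere(grid21, (10, 10, 10), 2.0, "s")
        with pytest.raises(EmptyStructureError):
            perturb(m, PerturbationSpec("erode", 5.0))

    def test_surface_noise_deterministic_and_boundary_limited(self, grid21):
        m = rasterize_sphere(grid21, (10, 10, 10), 6.0, "s")
        spec = PerturbationSpec("surface_noise", 0.5, seed=11)
        out1, out2 = perturb(m, spec), perturb(m, spec)
        np.testing.assert_array_equal(out1.voxels, out2.voxels)
        toggled = out1.voxels ^ m.voxels
        # Toggles happen only on the inner boundary or the outer shell.
        inner = boundary_voxels(m.voxels)
        from scipy import ndimage
        outer = ndimage.binary_dilation(m.voxels) & ~m.voxels
        assert not (toggled & ~(inner | outer)).any()
        assert toggled.sum() > 0

    def test_surface_noise_fraction_validated(self):
        with pytest.raises(ValueError):
            PerturbationSpec("surface_noise", 1.5)

    def test_translate_requires_axis(self):
        with pytest.raises(ValueError):
            PerturbationSpec("translate", 2.0)


def _tiny_spec(n=2, seed=0, perturbations=None):
    g = make_grid((32, 32, 32), (2, 2, 2))
    templates = (
        StructureTemplate("T", "target", "sphere", (8.0,)),
        StructureTemplate("O", "oar", "sphere", (5.0,), direction=(1, 0, 0),
                          gap_mm=4.0),
    )
    return CohortSpec(n_subjects=n, grid=g, templates=templates,
                      perturbations=perturbations or {}, seed=seed,
                      center_jitter_mm=1.0)


class TestCohort:
    def test_zero_perturbation_gives_identical_pairs(self):
        ms, as_ = simulate_subject(_tiny_spec(), 0)
        for name in ms.names:
            np.testing.assert_array_equal(ms[name].voxels, as_[name].voxels)

    def test_subject_generation_deterministic(self):
        spec = _tiny_spec(perturbations={
            "O": PerturbationSpec("surface_noise", 0.3)})
        a = simulate_subject(spec, 1)
        b = simulate_subject(spec, 1)
        for sa, sb in zip(a, b):
            for name in sa.names:
                np.testing.assert_array_equal(sa[name].voxels, sb[name].voxels)

    def test_distinct_seeds_differ(self):
        a_ms, _ = simulate_subject(_tiny_spec(seed=0), 0)
        b_ms, _ = simulate_subject(_tiny_spec(seed=1), 0)
        assert any(not np.array_equal(a_ms[n].voxels, b_ms[n].voxels)
                   for n in a_ms.names)

    def test_cohort_size_and_out_of_range_index(self):
        spec = _tiny_spec(n=3)
        assert len(simulate_cohort(spec)) == 3
        with pytest.raises(ValueError):
            simulate_subject(spec, 3)

    def test_unknown_perturbation_key_rejected(self):
        with pytest.raises(ValueError, match="nosuch"):
            _tiny_spec(perturbations={"nosuch": PerturbationSpec("dilate", 1.0)})

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError):
            _tiny_spec(n=0)
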