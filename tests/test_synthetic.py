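import numpy as np
import pytest

from extrafib.errors import EmptyRegionError, SceneConstructionError
from extrafib.geometry import UnitCellGeometry
from extrafib.pipeline import estimate_scene_partition
from extrafib.synthetic import (
    LABEL_PLATE,
    ProjectionImage,
    SceneConfig,
    VoxelScene,
    apply_vacancy,
    build_scene,
    cut_section,
    project,
    region_masks,
    sample_region_counts,
    simulate_edxs,
)

SMALL = SceneConfig(n_fibrils=3, n_periods=2, seed=11)


def _clipped_box_volume(plate, bounds):
    """Analytic volume of an axis-aligned plate clipped to the scene box."""
    dims = {plate.normal_axis: plate.thickness, 1 - plate.normal_axis: plate.width,
            2: plate.length}
    vol = 1.0
    for ax in range(3):
        half = dims[ax] / 2
        lo = max(0.0, plate.center[ax] - half)
        hi = min(bounds[ax], plate.center[ax] + half)
        vol *= max(0.0, hi - lo)
    return vol


class TestBuildScene:
    def test_bit_exact_reproducibility(self):
        a = build_scene(SMALL)
        b = build_scene(SMALL)
        assert np.array_equal(a.ca_density, b.ca_density)
        assert np.array_equal(a.labels, b.labels)
        assert a.plates == b.plates

    def test_seed_changes_plate_placement(self):
        a = build_scene(SMALL)
        b = build_scene(SMALL.replace(seed=12))
        assert a.plates != b.plates

    def test_plate_voxel_volume_matches_analytic_volume(self):
        """Voxelized plate volume agrees with the clipped cuboid volume.

        Uses plates no wider than the fibril so the vertical stacks cannot
        interpenetrate the over/underlying slabs (overlapping plate voxels
        merge, which would undercut a naive per-plate volume sum).
        """
        geom = UnitCellGeometry(plate_width=50.0)
        cfg = SMALL.replace(
            geometry=geom, plate_axis_dispersion=0.0, fill_corners=False
        )
        scene = build_scene(cfg)
        bounds = tuple(n * scene.voxel_size for n in scene.shape)
        expected = sum(_clipped_box_volume(p, bounds) for p in scene.plates)
        voxelized = scene.ground_truth["external_mineral"]
        assert voxelized == pytest.approx(expected, rel=0.02)

    def test_no_plates_all_mineral_is_intrafibrillar(self):
        cfg = SMALL.replace(
            plate_stack_depth=0, h_levels=0, fill_corners=False,
            gap_mineral_density=1.0,
        )
        truth = build_scene(cfg).ground_truth
        assert truth["external_mineral"] == 0.0
        assert truth["X_ext_true"] == 0.0

    def test_no_gap_mineral_is_fully_extrafibrillar(self):
        truth = build_scene(SMALL.replace(gap_mineral_density=0.0)).ground_truth
        assert truth["internal_mineral"] == 0.0
        assert truth["X_ext_true"] == 1.0

    def test_overfull_stack_raises_construction_error(self):
        with pytest.raises(SceneConstructionError):
            build_scene(SMALL.replace(plate_stack_depth=5))

    def test_hexagonal_packing_unsupported(self):
        with pytest.raises(SceneConstructionError):
            SceneConfig(lattice="hexagonal")

    def test_voxel_too_coarse_for_plates(self):
        with pytest.raises(SceneConstructionError):
            SceneConfig(voxel_size=3.0)

    def test_banding_in_registry_across_fibrils(self, default_scene):
        """Gap bands form continuous stripes across all fibril lanes."""
        g = default_scene.config.geometry
        labels = default_scene.labels
        iz_gap = int(g.gap_length / 2)  # mid-gap z index
        iz_ov = int(g.gap_length + g.overlap_length / 2)
        from extrafib.synthetic import LABEL_GAP, LABEL_OVERLAP

        fib = (labels[:, :, iz_gap] == LABEL_GAP) | (labels[:, :, iz_gap] == LABEL_OVERLAP)
        assert np.all(labels[:, :, iz_gap][fib] == LABEL_GAP)
        fib2 = (labels[:, :, iz_ov] == LABEL_GAP) | (labels[:, :, iz_ov] == LABEL_OVERLAP)
        assert np.all(labels[:, :, iz_ov][fib2] == LABEL_OVERLAP)


class TestCutSection:
    def test_full_thickness_cut_preserves_ground_truth(self, default_scene):
        whole = default_scene.ground_truth
        cut = cut_section(default_scene, (0, 0, 1), thickness=1e6, offset=-1.0)
        assert cut.ground_truth == pytest.approx(whole)

    def test_complementary_half_slabs_conserve_mineral(self, default_scene):
        nz = default_scene.shape[2] * default_scene.voxel_size
        lower = cut_section(default_scene, (0, 0, 1), thickness=nz / 2, offset=0.0)
        upper = cut_section(default_scene, (0, 0, 1), thickness=nz, offset=nz / 2)
        whole = default_scene.ground_truth
        for key in ("external_mineral", "internal_mineral"):
            total = lower.ground_truth[key] + upper.ground_truth[key]
            assert total == pytest.approx(whole[key], rel=1e-9)

    def test_oblique_slab_represents_whole_scene(self, default_scene):
        """A 45-degree slab samples the partition without strong bias."""
        n = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        Lx, _, Lz = (s * default_scene.voxel_size for s in default_scene.shape)
        center = (Lx / 2 + Lz / 2) / np.sqrt(2)
        slab = cut_section(default_scene, n, thickness=80.0, offset=center - 40.0)
        assert slab.ground_truth["X_ext_true"] == pytest.approx(
            default_scene.ground_truth["X_ext_true"], abs=0.05
        )

    def test_empty_slab_rejected(self, default_scene):
        with pytest.raises(ValueError):
            cut_section(default_scene, (0, 0, 1), thickness=5.0, offset=1e5)


class TestProject:
    def test_uniform_cube_projects_to_path_length(self):
        cube = VoxelScene(
            ca_density=np.ones((12, 12, 12), dtype=np.float32),
            labels=np.full((12, 12, 12), LABEL_PLATE, dtype=np.uint8),
            voxel_size=1.0,
            config=SMALL,
        )
        for axis in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            img = project(cube, axis)
            assert np.allclose(img.pixels, 12.0)

    def test_mass_conservation_along_principal_axes(self, default_scene):
        total = default_scene.ca_density.astype(np.float64).sum() * default_scene.voxel_size**3
        for axis in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            img = project(default_scene, axis)
            assert img.pixels.sum() * img.pixel_size**2 == pytest.approx(total, rel=1e-9)

    def test_oblique_projection_approximately_conserves_mass(self, default_scene):
        total = default_scene.ca_density.astype(np.float64).sum() * default_scene.voxel_size**3
        img = project(default_scene, (1, 0, 1))
        assert img.pixels.sum() * img.pixel_size**2 == pytest.approx(total, rel=0.02)

    def test_longitudinal_banding_has_d_period_autocorrelation(self, longitudinal):
        """Brute-force lag search finds the 67 nm repeat along the fibril axis."""
        profile = longitudinal.pixels.mean(axis=0)
        p = profile - profile.mean()
        acf = np.correlate(p, p, mode="full")[len(p) - 1 :]
        lags = np.arange(40, 95)
        best = lags[np.argmax(acf[lags])]
        assert abs(int(best) - 67) <= 1

    def test_cross_section_lacy_pattern(self, default_scene, cross_section):
        """Mineral wrappings project brighter than fibril interiors."""
        cfg = default_scene.config
        r = cfg.geometry.fibril_width / 2
        cy = cfg.geometry.section_thickness / 2
        ps = cross_section.pixel_size
        n0, n1 = cross_section.pixels.shape
        xs = (np.arange(n0) + 0.5) * ps
        ys = (np.arange(n1) + 0.5) * ps
        inside = np.zeros((n0, n1), dtype=bool)
        for i in range(cfg.n_fibrils):
            cx = (i + 0.5) * cfg.lattice_pitch
            inside |= (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= (r - 2) ** 2
        slab = np.zeros(n0, dtype=bool)
        for i in range(cfg.n_fibrils - 1):
            c0 = (i + 0.5) * cfg.lattice_pitch
            c1 = (i + 1.5) * cfg.lattice_pitch
            slab |= (xs > c0 + r) & (xs < c1 - r)
        plate_region = slab[:, None] & (np.abs(ys - cy) < 20)[None, :]
        assert cross_section.pixels[plate_region].mean() > cross_section.pixels[inside].mean()

    def test_vacancy_erodes_render_not_ground_truth(self):
        cfg = SMALL.replace(vacancy_fraction=0.5)
        scene = build_scene(cfg)
        assert len(scene.vacant_fibrils) == round(0.5 * cfg.n_fibrils)
        cross = project(scene, (0, 0, 1))
        eroded = apply_vacancy(cross, scene)
        assert eroded.pixels.sum() < cross.pixels.sum()
        assert scene.ground_truth["X_ext_true"] == build_scene(
            cfg.replace(vacancy_fraction=0.0)
        ).ground_truth["X_ext_true"]


class TestEdxs:
    def test_large_dose_limit_recovers_integrated_density(self, longitudinal):
        exact = simulate_edxs(longitudinal, dose_scale=100.0, noise=False)
        noisy = simulate_edxs(longitudinal, dose_scale=100.0, seed=3, noise=True)
        ratio = noisy.counts.sum() / exact.counts.sum()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_zero_density_region_never_counts(self):
        img = ProjectionImage(
            pixels=np.zeros((40, 40)), pixel_size=1.0, axis=(0, 1, 0)
        )
        cmap = simulate_edxs(img, seed=5)
        assert np.all(cmap.counts == 0)

    def test_count_rates_follow_reference_ordering(self, default_scene):
        """Noise-free rates order as stack > gap > overlap regions."""
        est = estimate_scene_partition(default_scene, noise=False)
        assert est["C_V"] > est["C_G"] > est["C_O"]

    def test_overlap_rate_is_purely_extrafibrillar(self, default_scene, longitudinal):
        """The O-region rate comes from plate mineral alone (the H slabs)."""
        plates_only = VoxelScene(
            ca_density=np.where(
                default_scene.labels == LABEL_PLATE, default_scene.ca_density, 0.0
            ).astype(np.float32),
            labels=default_scene.labels,
            voxel_size=default_scene.voxel_size,
            config=default_scene.config,
        )
        img_plates = project(plates_only, (0, 1, 0))
        masks = region_masks(default_scene.config, longitudinal)
        full = sample_region_counts(simulate_edxs(longitudinal, noise=False), masks["O"])
        isolated = sample_region_counts(simulate_edxs(img_plates, noise=False), masks["O"])
        assert full == pytest.approx(isolated, rel=1e-9)

    def test_gap_density_monotonically_decreases_estimate(self):
        xs = []
        for g in (0.3, 0.6, 0.9):
            scene = build_scene(SMALL.replace(gap_mineral_density=g))
            xs.append(estimate_scene_partition(scene, noise=False)["X_ext_estimate"])
        assert xs[0] > xs[1] > xs[2]

    def test_empty_region_mask_rejected(self, longitudinal):
        cmap = simulate_edxs(longitudinal, noise=False)
        with pytest.raises(EmptyRegionError):
            sample_region_counts(cmap, np.zeros_like(longitudinal.pixels, dtype=bool))

    def test_probe_subsampling_uses_requested_probes(self, default_scene, longitudinal):
        masks = region_masks(default_scene.config, longitudinal)
        cmap = simulate_edxs(longitudinal, noise=False)
        rng = np.random.default_rng(0)
        rate = sample_region_counts(cmap, masks["G"], n_probes=4, rng=rng)
        assert rate > 0
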