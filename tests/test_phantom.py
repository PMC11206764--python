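import numpy as np
import pytest

from mphsim.imaging_io import VoxelImage
from mphsim.phantom import (
    AIR,
    MUSCLE,
    TUMOR,
    Mask,
    MaterialProperties,
    Phantom,
    build_phantom,
    default_materials,
    signal_capture_fraction,
    threshold_segment,
    total_source_power,
)


@pytest.fixture
def ellipsoid_case():
    """Ellipsoidal tumor mask + Gaussian source on a 1 mm grid."""
    grid = VoxelImage(np.zeros((24, 24, 18)), (1.0, 1.0, 1.0))
    world = grid.world_grid()
    center = np.array([11.5, 11.5, 8.5])
    rel = (world - center) / np.array([4.0, 3.5, 3.0])
    tumor = np.sum(rel**2, axis=-1) <= 1.0
    d2 = np.sum((world - center) ** 2, axis=-1)
    source = 1e6 * np.exp(-d2 / (2 * 1.5**2))
    return Mask(tumor, grid), grid.copy_with(source)


class TestMaterials:
    def test_defaults_match_reference_tissue_table(self):
        mats = default_materials()
        muscle, tumor = mats["muscle"], mats["tumor"]
        assert (muscle.specific_heat, muscle.density, muscle.conductivity) == (
            3421.0, 1090.0, 0.49,
        )
        assert (tumor.specific_heat, tumor.density, tumor.conductivity) == (
            3760.0, 1045.0, 0.51,
        )
        for m in (muscle, tumor):
            assert m.electrical_conductivity == 0.23
            assert m.relative_permeability == 1.0
            assert m.relative_permittivity == 2000.0

    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            MaterialProperties(0.0, 3421, 0.49, 0.23)
        with pytest.raises(ValueError):
            MaterialProperties(1090, 3421, 0.49, 0.23, relative_permeability=0.5)


class TestThresholdSegment:
    def test_full_range_is_all_true(self, rng):
        img = VoxelImage(rng.uniform(0, 10, (6, 6, 6)), (1, 1, 1))
        mask = threshold_segment(img, img.values.min(), img.values.max())
        assert mask.values.all()

    def test_bound_above_max_warns_and_is_empty(self, rng):
        img = VoxelImage(rng.uniform(0, 10, (6, 6, 6)), (1, 1, 1))
        with pytest.warns(UserWarning, match="empty"):
            mask = threshold_segment(img, 100.0, 200.0)
        assert mask.voxel_count == 0

    def test_bounds_order_enforced(self, rng):
        img = VoxelImage(rng.uniform(0, 10, (4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="bound"):
            threshold_segment(img, 5.0, 1.0)

    def test_gaussian_blob_volume_matches_analytic(self):
        """Super-threshold volume of a Gaussian equals the analytic
        isosurface ball within one voxel shell."""
        grid = VoxelImage(np.zeros((40, 40, 40)), (1.0, 1.0, 1.0))
        world = grid.world_grid()
        sigma, amp = 4.0, 1.0
        d2 = np.sum((world - 19.5) ** 2, axis=-1)
        img = grid.copy_with(amp * np.exp(-d2 / (2 * sigma**2)))
        thr = 0.5
        mask = threshold_segment(img, thr, amp + 1)
        r_star = sigma * np.sqrt(2 * np.log(amp / thr))
        vol_analytic = 4 / 3 * np.pi * r_star**3
        shell = 4 * np.pi * r_star**2 * 1.0  # one voxel-layer shell
        assert abs(mask.volume_mm3 - vol_analytic) <= shell

    def test_monotone_in_lower_bound(self, rng):
        img = VoxelImage(rng.uniform(0, 10, (8, 8, 8)), (1, 1, 1))
        counts = [
            threshold_segment(img, lo, 10.0).voxel_count
            for lo in np.linspace(0, 9, 10)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_signal_capture_fraction(self, ellipsoid_case):
        tumor, src = ellipsoid_case
        assert signal_capture_fraction(src, tumor, 0.0) == pytest.approx(1.0)
        f_hi = signal_capture_fraction(src, tumor, 0.5e6)
        assert 0.0 < f_hi < 1.0


class TestBuildPhantom:
    def test_full_embedding(self, ellipsoid_case):
        tumor, src = ellipsoid_case
        ph = build_phantom(tumor, src, (22.0, 22.0, 14.0), embed_fraction=1.0)
        ks = np.argwhere(ph.labels == TUMOR)[:, 2]
        assert ks.max() < ph.muscle_top_k

    def test_default_third_embedding(self, ellipsoid_case):
        tumor, src = ellipsoid_case
        ph = build_phantom(tumor, src, (22.0, 22.0, 12.0))
        below = np.argwhere(ph.labels == TUMOR)[:, 2] < ph.muscle_top_k
        frac = below.mean()
        # within one voxel layer of tumor volume
        layer = (ph.labels == TUMOR).sum(axis=(0, 1)).max() / (ph.labels == TUMOR).sum()
        assert abs(frac - 1 / 3) <= layer

    def test_power_conservation_with_clipping(self, ellipsoid_case):
        tumor, src = ellipsoid_case
        ph = build_phantom(tumor, src, (22.0, 22.0, 12.0))
        voxel_m3 = ph.grid.voxel_volume_mm3 * 1e-9
        total_in = src.values.sum() * voxel_m3
        assert total_source_power(ph) + ph.clipped_power == pytest.approx(
            total_in, rel=1e-12
        )
        # the protruding tumor keeps its source; only air-fallen power clips
        assert ph.clipped_power >= 0

    def test_source_zero_in_air(self, ellipsoid_case):
        tumor, src = ellipsoid_case
        ph = build_phantom(tumor, src, (22.0, 22.0, 12.0))
        assert np.all(ph.source[ph.labels == AIR] == 0)

    def test_empty_tumor_rejected(self, ellipsoid_case):
        tumor, src = ellipsoid_case
        empty = Mask(np.zeros_like(tumor.values), tumor.grid)
        with pytest.raises(ValueError, match="empty"):
            build_phantom(empty, src, (22.0, 22.0, 12.0))

    def test_tumor_too_large_rejected(self, ellipsoid_case):
        tumor, src = ellipsoid_case
        with pytest.raises(ValueError, match="too large"):
            build_phantom(tumor, src, (6.0, 6.0, 12.0))


class TestTotalSourcePower:
    def test_zero_source(self):
        grid = VoxelImage(np.zeros((4, 4, 4)), (1, 1, 1))
        labels = np.full((4, 4, 4), MUSCLE, dtype=np.int8)
        ph = Phantom(labels, grid, default_materials(), np.zeros((4, 4, 4)))
        assert total_source_power(ph) == 0.0

    def test_uniform_source_arithmetic(self):
        # 100 voxels of (1 mm)^3 at 1e6 W/m^3 -> 0.1 W
        grid = VoxelImage(np.zeros((10, 10, 1)), (1, 1, 1))
        labels = np.full((10, 10, 1), TUMOR, dtype=np.int8)
        src = np.full((10, 10, 1), 1e6)
        ph = Phantom(labels, grid, default_materials(), src, embed_fraction=1.0)
        assert total_source_power(ph) == pytest.approx(0.1, rel=1e-12)

    def test_generator_blob_power_bookkeeping(self, clean_spec):
        """Total phantom power matches SLP x declared iron mass after the
        generate -> register -> calibrate -> segment -> build chain."""
        from mphsim.calibration import gv_to_power
        from mphsim.registration import estimate_transform, resample
        from mphsim.synthetic import generate_image_pair

        tracer, anat, fixed, moving, _ = generate_image_pair(clean_spec)
        t = estimate_transform(fixed, moving)
        reg = resample(tracer, t, anat)
        power = gv_to_power(reg, clean_spec.calibration_curve())
        tumor = threshold_segment(anat, 200.0, 600.0)
        ph = build_phantom(tumor, power, (24.0, 24.0, 12.0))
        expected_w = clean_spec.slp * clean_spec.total_fe_mass_mg * 1e-3
        realized = total_source_power(ph) + ph.clipped_power
        assert realized == pytest.approx(expected_w, rel=0.02)


def test_phantom_hdf5_round_trip(tmp_path, ellipsoid_case):
    tumor, src = ellipsoid_case
    ph = build_phantom(tumor, src, (22.0, 22.0, 12.0))
    ph.to_hdf5(tmp_path / "ph.h5")
    back = Phantom.from_hdf5(tmp_path / "ph.h5")
    assert np.array_equal(back.labels, ph.labels)
    assert np.allclose(back.source, ph.source)
    assert back.materials["tumor"].conductivity == 0.51
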