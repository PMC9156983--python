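import numpy as np
import pytest

from osteopore import (
    GenerationError,
    InputError,
    PhantomSpec,
    generate_cortical_phantom,
    generate_trabecular_phantom,
    render_section,
    run_cortical_pipeline,
    run_trabecular_pipeline,
)
from osteopore.phantom import spec_from_yaml, spec_to_yaml


def cortical_spec(**kwargs):
    defaults = dict(
        shape=(96, 96, 96),
        cortical_thickness_um=140.0,
        n_lacunae=8,
        n_canals=1,
        seed=7,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


class TestCorticalPhantom:
    def test_same_seed_is_bit_identical(self):
        v1, r1, t1 = generate_cortical_phantom(cortical_spec())
        v2, r2, t2 = generate_cortical_phantom(cortical_spec())
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert t1.lc_v_tv_pct == t2.lc_v_tv_pct

    def test_different_seeds_differ(self):
        v1, _, _ = generate_cortical_phantom(cortical_spec(seed=1))
        v2, _, _ = generate_cortical_phantom(cortical_spec(seed=2))
        assert not np.array_equal(v1.data, v2.data)

    def test_solid_control_has_zero_porosity(self):
        spec = cortical_spec(n_lacunae=0, n_canals=0, psf_sigma=0.0, noise_sd=0.0)
        result = run_cortical_pipeline(spec)
        m = result["micropore_metrics"]
        assert m.lc_v_tv_pct == 0.0
        assert m.ca_v_tv_pct == 0.0

    def test_truth_ledger_internally_consistent(self):
        _, roi, truth = generate_cortical_phantom(cortical_spec())
        tv_um3 = truth.roi_volume_mm3 * 1e9
        lc_sum = sum(l.volume_um3 for l in truth.lacunae)
        assert truth.lc_v_tv_pct == pytest.approx(100 * lc_sum / tv_um3, rel=1e-12)
        ca_sum = sum(c.volume_um3 for c in truth.canals)
        assert truth.ca_v_tv_pct == pytest.approx(100 * ca_sum / tv_um3, rel=1e-12)
        # ellipsoid volume is 4πabc/3 of the recorded semi-axes
        for lac in truth.lacunae:
            a, b, c = lac.semi_axes_um
            assert lac.volume_um3 == pytest.approx(4 / 3 * np.pi * a * b * c, rel=1e-12)
        assert truth.roi_volume_mm3 == pytest.approx(roi.voxel_count() * 8e-9, rel=1e-12)

    def test_clean_phantom_recovery_of_lacuna_count_and_porosity(self):
        # Fixed-volume lacunae, no blur or noise: count recovered exactly,
        # porosity within digitization tolerance of the analytic truth.
        spec = PhantomSpec(
            shape=(140, 140, 140),
            cortical_thickness_um=220.0,
            n_lacunae=20,
            lacuna_volume_range=(300.0, 300.0),
            n_canals=0,
            psf_sigma=0.0,
            noise_sd=0.0,
            seed=11,
        )
        result = run_cortical_pipeline(spec)
        truth = result["truth"]
        m = result["micropore_metrics"]
        table = result["pore_table"]
        assert (table["pore_class"] == "lacuna").sum() == 20
        assert m.lc_v_tv_pct == pytest.approx(truth.lc_v_tv_pct, rel=0.15)

    def test_placement_failure_raises_generation_error(self):
        spec = cortical_spec(shape=(40, 40, 40), cortical_thickness_um=60.0, n_lacunae=400)
        with pytest.raises(GenerationError):
            generate_cortical_phantom(spec)

    def test_band_does_not_fit_rejected(self):
        with pytest.raises(InputError):
            generate_cortical_phantom(cortical_spec(cortical_thickness_um=10000.0))


class TestTrabecularPhantom:
    def test_plate_lattice_bvtv_and_thickness_exact(self):
        spec = PhantomSpec(
            shape=(90, 40, 40),
            lattice="plates",
            plate_thickness_um=12.0,
            plate_gap_um=24.0,
            psf_sigma=0.0,
            noise_sd=0.0,
            seed=3,
        )
        _, _, truth = generate_trabecular_phantom(spec)
        assert truth.bv_tv == pytest.approx(12.0 / 36.0, rel=1e-12)
        assert truth.tb_th_um == 12.0
        result = run_trabecular_pipeline(spec)
        assert result["morphometry"].bv_tv == pytest.approx(truth.bv_tv, rel=1e-12)

    def test_rod_lattice_thickness_recovered(self):
        spec = PhantomSpec(
            shape=(120, 120, 120),
            lattice="rods",
            rod_radius_um=30.0,
            lattice_pitch_um=240.0,
            psf_sigma=0.0,
            noise_sd=0.0,
            seed=3,
        )
        _, _, truth = generate_trabecular_phantom(spec)
        assert truth.tb_th_um == 60.0
        result = run_trabecular_pipeline(spec)
        m = result["morphometry"]
        # thickness within ±1 voxel; BV/TV within a few percent of the
        # inclusion-exclusion truth (digitization at rod junctions)
        assert abs(m.tb_th_mm * 1000 - 60.0) <= 8.0
        assert m.bv_tv == pytest.approx(truth.bv_tv, rel=0.10)

    def test_rod_radius_must_fit_pitch(self):
        with pytest.raises(InputError):
            PhantomSpec(lattice="rods", rod_radius_um=130.0, lattice_pitch_um=240.0)

    def test_gap_exceeding_domain_leaves_single_plate(self):
        # One 1-voxel plate in 30 slices: BV/TV is exactly 1/30.
        spec = PhantomSpec(
            shape=(30, 20, 20),
            lattice="plates",
            plate_thickness_um=2.0,
            plate_gap_um=1000.0,
            psf_sigma=0.0,
            noise_sd=0.0,
        )
        _, _, truth = generate_trabecular_phantom(spec)
        assert truth.bv_tv == pytest.approx(1 / 30, rel=1e-12)


class TestRenderSection:
    def test_solid_slice_is_constant(self):
        spec = cortical_spec(n_lacunae=0, n_canals=0, psf_sigma=0.0, noise_sd=0.0, density_sd=0.0)
        vol, _, _ = generate_cortical_phantom(spec)
        img = render_section(vol, 10)
        band = img.pixels[:, 30:60]
        assert np.allclose(band, band[0, 0])

    def test_grey_range_spans_0_255(self):
        vol, _, _ = generate_cortical_phantom(cortical_spec(noise_sd=0.0, psf_sigma=0.0))
        img = render_section(vol, 48)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 255.0

    def test_section_through_ellipsoid_center_matches_analytic_intersection(self):
        # One axis-aligned-ish lacuna; slice through its center shows an
        # ellipse whose area matches the analytic plane cut within ~1 px rim.
        spec = PhantomSpec(
            shape=(80, 80, 80),
            cortical_thickness_um=150.0,
            n_lacunae=1,
            lacuna_volume_range=(600.0, 600.0),
            n_canals=0,
            psf_sigma=0.0,
            noise_sd=0.0,
            density_sd=0.0,
            seed=5,
        )
        vol, roi, truth = generate_cortical_phantom(spec)
        lac = truth.lacunae[0]
        z0 = int(round(lac.center_vox[0]))
        img = render_section(vol, z0)
        dark = (img.pixels < 100.0) & roi.mask[z0]  # pores only, not background
        # the voxelized cut through (near) the center cannot exceed the
        # largest analytic cross-section πab and must be a substantial cut
        a, b, _ = lac.semi_axes_um
        max_cut_px = np.pi * (a / 2.0) * (b / 2.0)  # µm² / (2 µm)² px area
        assert 0 < dark.sum() <= max_cut_px * 1.5

    def test_out_of_range_slice_rejected(self):
        vol, _, _ = generate_cortical_phantom(cortical_spec())
        with pytest.raises(InputError):
            render_section(vol, 96)


class TestSpecYaml:
    def test_yaml_round_trip(self, tmp_path):
        spec = cortical_spec(seed=42)
        spec_to_yaml(spec, tmp_path / "spec.yaml")
        back = spec_from_yaml(tmp_path / "spec.yaml")
        assert back == spec
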