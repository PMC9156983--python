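import numpy as np
import pandas as pd
import pytest
from _util import flood_fill_components, solid_cylinder

from osteopore import (
    DimensionError,
    InputError,
    canal_diameter,
    extract_pores,
    label_pores,
    microporosity_metrics,
)
from osteopore.micropore import classify_volume


class TestExtractPores:
    def test_solid_bone_has_no_pores(self):
        roi = np.ones((8, 8, 8), dtype=bool)
        assert not extract_pores(roi.copy(), roi).any()

    def test_carved_cube_yields_exact_pore_voxels(self):
        roi = np.ones((12, 12, 12), dtype=bool)
        bone = roi.copy()
        bone[3:8, 3:8, 3:8] = False
        pores = extract_pores(bone, roi)
        assert pores.sum() == 125

    def test_empty_bone_gives_pore_mask_equal_to_roi(self):
        roi = np.zeros((8, 8, 8), dtype=bool)
        roi[2:6] = True
        pores = extract_pores(np.zeros_like(roi), roi)
        np.testing.assert_array_equal(pores, roi)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            extract_pores(np.ones((4, 4, 4), bool), np.ones((5, 4, 4), bool))


class TestClassification:
    # At 2 µm voxels: 1 voxel = 8 µm³, 4³ = 512 µm³, 7³ = 2744 µm³.
    @pytest.mark.parametrize(
        "volume_um3,expected",
        [
            (8.0, "noise"),
            (99.9, "noise"),
            (100.0, "lacuna"),  # inclusive lower bound
            (512.0, "lacuna"),
            (1500.0, "lacuna"),  # inclusive upper bound
            (1500.1, "canal"),
            (2744.0, "canal"),
        ],
    )
    def test_volume_class_boundaries(self, volume_um3, expected):
        assert classify_volume(volume_um3) == expected

    def test_voxel_components_classified_by_physical_volume(self):
        mask = np.zeros((24, 24, 24), dtype=bool)
        mask[1, 1, 1] = True  # 8 µm³ → noise
        mask[4:8, 4:8, 4:8] = True  # 512 µm³ → lacuna
        mask[12:19, 12:19, 12:19] = True  # 2744 µm³ → canal
        table = label_pores(mask, voxel_size=2.0)
        assert sorted(table["pore_class"]) == ["canal", "lacuna", "noise"]
        by_class = table.set_index("pore_class")["volume_um3"]
        assert by_class["noise"] == 8.0
        assert by_class["lacuna"] == 512.0
        assert by_class["canal"] == 2744.0

    def test_diagonal_pair_is_one_component(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = mask[2, 2, 2] = True
        table = label_pores(mask, voxel_size=2.0)
        assert len(table) == 1
        assert table["voxel_count"][0] == 2


class TestLabelingOracle:
    def test_matches_flood_fill_on_random_masks(self, rng):
        for _ in range(5):
            mask = rng.random((24, 24, 24)) < 0.25
            table = label_pores(mask, voxel_size=2.0)
            assert sorted(table["voxel_count"]) == flood_fill_components(mask)

    def test_partition_property(self, rng):
        mask = rng.random((32, 32, 32)) < 0.3
        table = label_pores(mask, voxel_size=2.0)
        assert table["voxel_count"].sum() == mask.sum()

    def test_border_touching_flag_against_roi(self):
        roi = np.ones((10, 10, 10), dtype=bool)
        mask = np.zeros_like(roi)
        mask[0, 0, 0] = True  # on ROI border
        mask[4:6, 4:6, 4:6] = True  # interior
        table = label_pores(mask, voxel_size=2.0, roi=roi)
        flags = table.sort_values("voxel_count")["border_touching"].tolist()
        assert flags == [True, False]


class TestCanalDiameter:
    def test_digitized_cylinder_recovers_analytic_diameter(self):
        # radius 10 µm = 5 voxels at 2 µm, length 100 voxels.
        mask = solid_cylinder((110, 16, 16), axis_len=100, radius=5.0)
        d = canal_diameter(mask, voxel_size=2.0)
        assert abs(d - 20.0) <= 4.0  # ± 2 voxel widths

    def test_single_voxel_degenerate(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        d = canal_diameter(mask, voxel_size=2.0)
        assert abs(d - 2.0) <= 2.0  # voxel_size ± 1 voxel

    def test_sphere_diameter_converges_with_resolution(self):
        r_um = 20.0
        errors = []
        for vs in (4.0, 2.0, 1.0):
            r_vox = r_um / vs
            n = int(2 * r_vox + 5)
            g = np.mgrid[0:n, 0:n, 0:n].astype(float)
            c = (n - 1) / 2.0
            mask = ((g - c) ** 2).sum(axis=0) <= r_vox**2
            d = canal_diameter(mask, voxel_size=vs)
            errors.append(abs(d - 2 * r_um))
        assert errors[-1] <= errors[0]
        assert errors[-1] <= 2.0  # within ~2 voxels at the finest grid

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            canal_diameter(np.zeros((4, 4, 4), bool), voxel_size=2.0)

    def test_two_components_rejected(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[1, 1, 1] = mask[6, 6, 6] = True
        with pytest.raises(InputError):
            canal_diameter(mask, voxel_size=2.0)


def make_table(rows):
    defaults = dict(
        label=0, voxel_count=1, volume_um3=8.0, pore_class="noise",
        centroid_z=0.0, centroid_y=0.0, centroid_x=0.0,
        diameter_um=np.nan, border_touching=False,
    )
    return pd.DataFrame([{**defaults, **r, "label": i + 1} for i, r in enumerate(rows)])


class TestMicroporosityMetrics:
    def test_hand_arithmetic_lacunar_metrics(self):
        # ROI of 0.001 mm³ (50³ voxels at 2 µm); 10 lacunae totalling
        # 4×10⁻⁷ mm³ → Lc.V/TV = 0.04 %, N.Lc = 10,000 /mm³.
        roi = np.ones((50, 50, 50), dtype=bool)
        rows = [{"pore_class": "lacuna", "volume_um3": 40.0} for _ in range(10)]
        m = microporosity_metrics(make_table(rows), roi, voxel_size=2.0)
        assert m.lc_v_tv_pct == pytest.approx(0.04, rel=1e-12)
        assert m.n_lc_per_mm3 == pytest.approx(10_000.0, rel=1e-12)
        assert m.tv_mm3 == pytest.approx(0.001, rel=1e-12)

    def test_no_canals_gives_zero_porosity_and_nan_diameter(self):
        roi = np.ones((10, 10, 10), dtype=bool)
        rows = [{"pore_class": "lacuna", "volume_um3": 200.0}]
        m = microporosity_metrics(make_table(rows), roi, voxel_size=2.0)
        assert m.ca_v_tv_pct == 0.0
        assert m.n_ca_per_mm3 == 0.0
        assert np.isnan(m.ca_dm_um)

    def test_single_canal_exact_porosity(self):
        roi = np.ones((10, 10, 10), dtype=bool)
        tv_um3 = 1000 * 8.0
        rows = [{"pore_class": "canal", "volume_um3": 2000.0, "diameter_um": 30.0}]
        m = microporosity_metrics(make_table(rows), roi, voxel_size=2.0)
        assert m.ca_v_tv_pct == pytest.approx(100 * 2000.0 / tv_um3, rel=1e-12)
        assert m.ca_dm_um == 30.0

    def test_noise_excluded_from_numerators(self):
        roi = np.ones((10, 10, 10), dtype=bool)
        rows = [
            {"pore_class": "noise", "volume_um3": 8.0},
            {"pore_class": "lacuna", "volume_um3": 200.0},
        ]
        m = microporosity_metrics(make_table(rows), roi, voxel_size=2.0)
        assert m.lc_v_tv_pct == pytest.approx(100 * 200.0 / 8000.0)
        assert m.n_lc_per_mm3 == pytest.approx(1 / (8000.0 * 1e-9))

    def test_adding_a_pore_never_decreases_porosity(self):
        roi = np.ones((10, 10, 10), dtype=bool)
        rows = [{"pore_class": "lacuna", "volume_um3": 200.0}]
        m1 = microporosity_metrics(make_table(rows), roi, voxel_size=2.0)
        rows.append({"pore_class": "lacuna", "volume_um3": 150.0})
        m2 = microporosity_metrics(make_table(rows), roi, voxel_size=2.0)
        assert m2.lc_v_tv_pct >= m1.lc_v_tv_pct

    def test_exclude_border_drops_flagged_pores(self):
        roi = np.ones((10, 10, 10), dtype=bool)
        rows = [
            {"pore_class": "lacuna", "volume_um3": 200.0, "border_touching": True},
            {"pore_class": "lacuna", "volume_um3": 300.0},
        ]
        m = microporosity_metrics(make_table(rows), roi, voxel_size=2.0, include_border=False)
        assert m.lc_v_tv_pct == pytest.approx(100 * 300.0 / 8000.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(InputError):
            microporosity_metrics(make_table([]), np.zeros((4, 4, 4), bool), 2.0)
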