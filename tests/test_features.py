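import numpy as np
import pytest

from flpet import (
    FeatureConfig,
    LesionSpec,
    PhantomSpec,
    SuvVolume,
    feature_panel,
    make_phantom,
    segment_lesions,
)
from flpet.features import (
    dmax,
    it_erosion,
    med_edge,
    med_pcd,
    suv_statistics,
    tlg,
    tmtv,
    tmts,
    tumbb,
    tvsr,
)
from flpet.segmentation import lesion_set_from_labels

from conftest import random_lesion_set
from _oracles import (
    brute_erosion_count,
    brute_max_pairwise,
    brute_surface_voxels,
    brute_voxel_face_area,
)


def cube_lesions(side=10, spacing=(1.0, 1.0, 1.0), suv=5.0, grid=20):
    vals = np.zeros((grid, grid, grid))
    labels = np.zeros((grid, grid, grid), int)
    vals[2:2 + side, 2:2 + side, 2:2 + side] = suv
    labels[2:2 + side, 2:2 + side, 2:2 + side] = 1
    return SuvVolume(values=vals, spacing=spacing), lesion_set_from_labels(labels, spacing, vals)


def sphere_set(radius, spacing=1.0, suv=10.0):
    n = int(2 * radius / spacing) + 9
    spec = PhantomSpec(
        shape=(n, n, n), spacing=(spacing,) * 3, background_suv=0.0, noise_sd=0.0,
        lesions=[LesionSpec("sphere", ((n - 1) * spacing / 2,) * 3, radius, suv)],
    )
    vol, truth, _ = make_phantom(spec)
    return vol, lesion_set_from_labels(truth.labels, vol.spacing, vol.values)


class TestSimpleFeatures:
    def test_uniform_cube_suv_stats(self):
        vol, lesions = cube_lesions(suv=5.0)
        assert suv_statistics(vol, lesions) == (5.0, 5.0)

    def test_two_value_suv_stats(self):
        vol, lesions = cube_lesions(side=2, suv=4.0)
        vol.values[2, 2, 2] = 6.0
        smax, smean = suv_statistics(vol, lesions)
        assert smax == 6.0 and smean == pytest.approx((4.0 * 7 + 6.0) / 8)

    def test_tmtv_voxel_arithmetic(self):
        vals = np.zeros((12, 12, 12))
        vals[1:11, 1:11, 1:11] = 3.0  # 1000 voxels
        labels = (vals > 0).astype(int)
        lesions = lesion_set_from_labels(labels, (2.0, 2.0, 2.0), vals)
        assert tmtv(lesions) == pytest.approx(8.0)

    def test_tmtv_additive_over_lesions(self):
        vals = np.zeros((20, 10, 10))
        vals[1:4, 1:4, 1:4] = 5.0
        vals[10:16, 1:5, 1:5] = 5.0
        labels = np.zeros_like(vals, int)
        labels[1:4, 1:4, 1:4] = 1
        labels[10:16, 1:5, 1:5] = 2
        lesions = lesion_set_from_labels(labels, (1, 1, 1), vals)
        assert tmtv(lesions) == pytest.approx((27 + 96) / 1000)

    def test_tlg_uniform(self):
        vol, lesions = cube_lesions(side=10, suv=5.0)  # 1000 voxels = 1 cm3
        assert tlg(vol, lesions) == pytest.approx(5.0)

    def test_cube_voxel_faces_exact(self):
        _, lesions = cube_lesions(side=20, grid=26)
        area = tmts(lesions, FeatureConfig(surface_method="voxel_faces"))
        assert area == pytest.approx(24.0)

    def test_tvsr_arithmetic(self):
        assert tvsr(1.0, 2.0) == pytest.approx(5.0)  # 1000 mm3 / 200 mm2

    def test_tvsr_zero_surface_raises(self):
        with pytest.raises(ValueError):
            tvsr(1.0, 0.0)

    def test_tumbb_cube_and_corners(self):
        _, lesions = cube_lesions(side=10)
        assert tumbb(lesions) == pytest.approx(1.0)
        vals = np.zeros((100, 100, 100))
        labels = np.zeros_like(vals, int)
        labels[0, 0, 0] = 1
        labels[99, 99, 99] = 2
        corner = lesion_set_from_labels(labels, (1, 1, 1), vals)
        assert tumbb(corner) == pytest.approx(1000.0)

    def test_single_voxel_dmax_zero_and_erosion_one(self):
        vals = np.zeros((5, 5, 5))
        labels = np.zeros_like(vals, int)
        labels[2, 2, 2] = 1
        lesions = lesion_set_from_labels(labels, (1, 1, 1), vals)
        assert dmax(lesions) == 0.0
        assert it_erosion(lesions) == 1.0

    def test_erosion_cube_ceil_half_side(self):
        _, lesions = cube_lesions(side=9, grid=15)
        assert it_erosion(lesions) == 5.0  # 26-neighborhood: ceil(9/2)

    def test_erosion_volume_weighted_mean(self):
        # lesion A: single voxel (1 iteration, 1 mm3 at unit spacing);
        # lesion B: 3x3x3 cube (2 iterations, 27 mm3)
        vals = np.zeros((12, 8, 8))
        labels = np.zeros_like(vals, int)
        labels[1, 1, 1] = 1
        labels[5:8, 2:5, 2:5] = 2
        lesions = lesion_set_from_labels(labels, (1, 1, 1), vals)
        assert it_erosion(lesions) == pytest.approx((1 * 1 + 2 * 27) / 28)
        assert it_erosion(lesions, FeatureConfig(iterosion_aggregation="mean")) == pytest.approx(1.5)


class TestSphereGeometry:
    def test_sphere_analytic_panel(self):
        vol, lesions = sphere_set(15.0)
        panel = feature_panel(vol, lesions)
        assert panel.tmtv_cm3 == pytest.approx(4 / 3 * np.pi * 15**3 / 1000, rel=0.02)
        assert panel.tvsr_mm == pytest.approx(5.0, rel=0.03)
        assert panel.med_pcd_mm == pytest.approx(15.0, abs=0.5)
        assert panel.n_roi == 1
        assert panel.dmax_mm == pytest.approx(30.0, abs=1.0)
        assert panel.med_edge_mm == pytest.approx(30.0, abs=1.0)

    def test_fragmentation_lowers_tvsr(self):
        # one sphere vs two spheres of half volume each (equal total volume)
        r = 15.0
        r_half = r / 2 ** (1 / 3)
        vol1, l1 = sphere_set(r)
        spec = PhantomSpec(
            shape=(70, 40, 40), spacing=(1, 1, 1), background_suv=0.0, noise_sd=0.0,
            lesions=[LesionSpec("sphere", (17, 19, 19), r_half, 10.0),
                     LesionSpec("sphere", (51, 19, 19), r_half, 10.0)],
        )
        vol2, truth2, _ = make_phantom(spec)
        l2 = lesion_set_from_labels(truth2.labels, vol2.spacing, vol2.values)
        v1, s1 = tmtv(l1), tmts(l1)
        v2, s2 = tmtv(l2), tmts(l2)
        assert v2 == pytest.approx(v1, rel=0.02)
        assert tvsr(v2, s2) < tvsr(v1, s1)

    def test_two_identical_spheres_same_medpcd(self):
        _, l1 = sphere_set(12.0)
        spec = PhantomSpec(
            shape=(64, 40, 40), spacing=(1, 1, 1), background_suv=0.0, noise_sd=0.0,
            lesions=[LesionSpec("sphere", (15, 19, 19), 12.0, 10.0),
                     LesionSpec("sphere", (47, 19, 19), 12.0, 10.0)],
        )
        vol2, truth2, _ = make_phantom(spec)
        l2 = lesion_set_from_labels(truth2.labels, vol2.spacing, vol2.values)
        assert med_pcd(l2) == pytest.approx(med_pcd(l1), abs=1e-9)

    def test_single_lesion_mededge_equals_dmax(self, sphere_panel):
        assert sphere_panel.med_edge_mm == pytest.approx(sphere_panel.dmax_mm, abs=1e-9)

    def test_three_spheres_median_diameter(self):
        spec = PhantomSpec(
            shape=(110, 44, 44), spacing=(1, 1, 1), background_suv=0.0, noise_sd=0.0,
            lesions=[LesionSpec("sphere", (12, 21, 21), 5.0, 10.0),
                     LesionSpec("sphere", (42, 21, 21), 10.0, 10.0),
                     LesionSpec("sphere", (85, 21, 21), 15.0, 10.0)],
        )
        vol, truth, _ = make_phantom(spec)
        lesions = lesion_set_from_labels(truth.labels, vol.spacing, vol.values)
        assert med_edge(lesions) == pytest.approx(20.0, abs=1.0)

    def test_two_sphere_dmax_geometry(self):
        spec = PhantomSpec(
            shape=(80, 50, 50), spacing=(1, 1, 1), background_suv=0.0, noise_sd=0.0,
            lesions=[LesionSpec("sphere", (20, 24, 24), 10.0, 10.0),
                     LesionSpec("sphere", (60, 24, 24), 8.0, 10.0)],
        )
        vol, truth, exp = make_phantom(spec)
        lesions = lesion_set_from_labels(truth.labels, vol.spacing, vol.values)
        assert exp["dmax_mm"] == pytest.approx(40 + 10 + 8)
        assert dmax(lesions) == pytest.approx(exp["dmax_mm"], abs=1.0)

    @pytest.mark.parametrize("spacing", [2.0, 1.0, 0.5])
    def test_sphere_convergence_with_spacing(self, spacing):
        vol, lesions = sphere_set(12.0, spacing=spacing)
        tol = 0.08 * spacing  # finer grids must be closer
        assert tmtv(lesions) == pytest.approx(4 / 3 * np.pi * 12**3 / 1000, rel=tol + 0.01)
        assert med_pcd(lesions) == pytest.approx(12.0, abs=0.6 * spacing)


class TestIdentitiesAndEquivariance:
    def test_tlg_identity_on_random_phantom(self, rng):
        lesions, suv = random_lesion_set(rng)
        vol = SuvVolume(values=suv, spacing=(1, 1, 1))
        smax, smean = suv_statistics(vol, lesions)
        assert tlg(vol, lesions) == pytest.approx(tmtv(lesions) * smean, rel=1e-9)

    def test_tumbb_contains_tmtv(self, rng):
        lesions, _ = random_lesion_set(rng, n_lesions=3)
        assert tumbb(lesions) >= tmtv(lesions)

    @pytest.mark.parametrize("scale", [0.5, 2.0])
    def test_scale_equivariance(self, rng, scale):
        lesions, suv = random_lesion_set(rng)
        vol = SuvVolume(values=suv, spacing=(1, 1, 1))
        scaled_lesions, _ = random_lesion_set(np.random.default_rng(20240405))
        scaled_lesions.spacing = (scale, scale, scale)
        for les in scaled_lesions:
            les.volume_mm3 *= scale**3
            les.centroid_mm *= scale
        vol_s = SuvVolume(values=suv, spacing=(scale,) * 3)
        assert tmtv(scaled_lesions) == pytest.approx(tmtv(lesions) * scale**3, rel=1e-9)
        assert tmts(scaled_lesions) == pytest.approx(tmts(lesions) * scale**2, rel=1e-6)
        assert dmax(scaled_lesions) == pytest.approx(dmax(lesions) * scale, rel=1e-9)
        assert med_pcd(scaled_lesions) == pytest.approx(med_pcd(lesions) * scale, rel=1e-9)
        assert suv_statistics(vol_s, scaled_lesions) == suv_statistics(vol, lesions)

    def test_panel_deterministic(self, sphere_phantom):
        vol, truth, _ = sphere_phantom
        lesions = lesion_set_from_labels(truth.labels, vol.spacing, vol.values)
        p1 = feature_panel(vol, lesions).as_dict()
        p2 = feature_panel(vol, lesions).as_dict()
        assert p1 == p2

    def test_empty_lesion_set_raises(self):
        vol = SuvVolume(values=np.zeros((5, 5, 5)), spacing=(1, 1, 1))
        empty = lesion_set_from_labels(np.zeros((5, 5, 5), int), (1, 1, 1), vol.values)
        with pytest.raises(ValueError):
            feature_panel(vol, empty)


class TestBruteForceEquivalence:
    """Every feature on small random masks equals an independent loop implementation."""

    @pytest.fixture(params=[0, 1, 2], ids=["maskA", "maskB", "maskC"])
    def case(self, request):
        rng = np.random.default_rng(1000 + request.param)
        lesions, suv = random_lesion_set(rng, n_lesions=1 + request.param % 3)
        return lesions, SuvVolume(values=suv, spacing=(1, 1, 1))

    def test_suv_and_volume_features(self, case):
        lesions, vol = case
        allvox = np.concatenate([l.voxels for l in lesions])
        vals = [vol.values[tuple(v)] for v in allvox]
        assert suv_statistics(vol, lesions) == (pytest.approx(max(vals)), pytest.approx(np.mean(vals)))
        assert tmtv(lesions) == pytest.approx(len(allvox) / 1000)
        assert tlg(vol, lesions) == pytest.approx(sum(vals) / 1000)

    def test_surface_area_voxel_faces(self, case):
        lesions, _ = case
        oracle = sum(brute_voxel_face_area(l.voxels, (1, 1, 1)) for l in lesions)
        assert tmts(lesions, FeatureConfig(surface_method="voxel_faces")) == pytest.approx(oracle / 100)

    def test_surface_voxel_definition(self, case):
        lesions, _ = case
        for les in lesions:
            oracle = brute_surface_voxels(les.voxels)
            assert sorted(map(tuple, les.surface_voxels)) == sorted(map(tuple, oracle))

    def test_dmax_all_pairs(self, case):
        lesions, _ = case
        allvox = np.concatenate([l.voxels for l in lesions]).astype(float)
        assert dmax(lesions) == pytest.approx(brute_max_pairwise(allvox), rel=1e-12)

    def test_med_pcd_enumeration(self, case):
        lesions, _ = case
        dists = []
        for les in lesions:
            centroid = les.voxels.mean(axis=0)
            for sv in brute_surface_voxels(les.voxels):
                dists.append(np.linalg.norm(sv - centroid))
        assert med_pcd(lesions) == pytest.approx(np.median(dists), rel=1e-12)

    def test_med_edge_per_lesion_all_pairs(self, case):
        lesions, _ = case
        diams = [brute_max_pairwise(brute_surface_voxels(l.voxels).astype(float)) for l in lesions]
        assert med_edge(lesions) == pytest.approx(np.median(diams), rel=1e-12)

    @pytest.mark.parametrize("element", [6, 26])
    def test_iterated_erosion(self, case, element):
        lesions, _ = case
        counts = [brute_erosion_count(l.voxels, element) for l in lesions]
        weights = [l.volume_mm3 for l in lesions]
        oracle = np.average(counts, weights=weights)
        got = it_erosion(lesions, FeatureConfig(erosion_structuring_element=element))
        assert got == pytest.approx(oracle)


def test_ellipsoid_medpcd_matches_enumeration():
    spec = PhantomSpec(
        shape=(50, 50, 50), spacing=(1, 1, 1), background_suv=0.0, noise_sd=0.0,
        lesions=[LesionSpec("ellipsoid", (24, 24, 24), (10, 15, 20), 10.0)],
    )
    vol, truth, _ = make_phantom(spec)
    lesions = lesion_set_from_labels(truth.labels, vol.spacing, vol.values)
    les = lesions.lesions[0]
    centroid = les.voxels.mean(axis=0)
    oracle = np.median([np.linalg.norm(sv - centroid) for sv in brute_surface_voxels(les.voxels)])
    assert med_pcd(lesions) == pytest.approx(oracle, rel=1e-12)
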