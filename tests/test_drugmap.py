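"""Drug-channel quantification: stack normalization, iterative
signal/background thresholding against an exhaustive oracle, fold changes,
geodesic extravasation distances and per-class attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from conftest import cylinder_mask
from fusvasc import drugmap, synthgen, vesselmap
from fusvasc.core import ImageVolume
from fusvasc.drugmap import (
    attribute_to_vessel_class,
    brute_force_otsu,
    distance_histogram,
    extravasation_distance,
    fold_change,
    intensity_gradient,
    preprocess_drug,
    tissue_threshold,
)


def _volume(arr, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(arr, float), spacing, "drug")


class TestPreprocessDrug:
    def test_multiplicative_fade_normalized(self, rng):
        base = rng.uniform(80, 180, size=(64, 64))
        fade = np.linspace(1.0, 0.4, 10)
        stack = _volume(np.stack([base * f for f in fade]))
        out = preprocess_drug(stack)
        means = out.voxels.mean(axis=(1, 2))
        assert np.all(np.abs(means - means[0]) / means[0] < 0.05)

    def test_identical_slices_unchanged_up_to_scale(self, rng):
        plane = rng.uniform(50, 150, size=(48, 48))
        stack = _volume(np.stack([plane] * 5))
        cfg = vesselmap.PreprocessConfig(
            gaussian_radius_vox=1, contrast_mode="scale"
        )
        out = preprocess_drug(stack, cfg)
        ratio = out.voxels / stack.voxels
        # a pure gain: all slices scaled by one constant (up to smoothing)
        assert np.all(out.voxels[0] == out.voxels[2])

    def test_constant_stack_stays_constant(self):
        out = preprocess_drug(_volume(np.full((4, 32, 32), 9.0)))
        assert np.ptp(out.voxels) == 0

    def test_single_slice_passthrough_warns(self):
        with pytest.warns(UserWarning):
            preprocess_drug(_volume(np.random.default_rng(0).random((1, 32, 32))))


class TestTissueThreshold:
    def test_two_gaussian_mixture_matches_exhaustive_minimizer(self, rng):
        vals = np.concatenate(
            [rng.normal(100, 10, 4000), rng.normal(200, 10, 4000)]
        )
        img = _volume(vals.reshape(2, 40, 100))
        thr, _ = tissue_threshold(
            img, np.ones(img.shape, bool), rolling_ball_radius_vox=None
        )
        oracle = brute_force_otsu(vals)
        assert abs(thr.threshold_value - oracle) <= 1.0

    def test_background_only_phantom_low_suprathreshold_fraction(self, rng):
        vals = rng.normal(100, 5, size=(8, 64, 64))
        img = _volume(np.clip(vals, 0, None))
        thr, flat = tissue_threshold(
            img, np.ones(img.shape, bool), rolling_ball_radius_vox=None
        )
        assert thr.weak_separation
        frac = (flat.voxels > thr.threshold_value).mean()
        assert frac < 0.02

    def test_iteration_cap_flags_non_convergence(self, rng):
        vals = np.concatenate(
            [rng.normal(100, 10, 4000), rng.normal(160, 30, 4000)]
        )
        img = _volume(vals.reshape(2, 40, 100))
        thr, _ = tissue_threshold(
            img, np.ones(img.shape, bool),
            rolling_ball_radius_vox=None, tol=0.0, max_iter=4,
        )
        assert thr.iterations_run == 4
        assert not thr.converged

    def test_constant_tissue_degenerate(self):
        img = _volume(np.full((4, 32, 32), 7.0))
        with pytest.raises(ValueError):
            tissue_threshold(img, np.ones(img.shape, bool), rolling_ball_radius_vox=None)

    def test_empty_tissue_mask(self):
        img = _volume(np.random.default_rng(0).random((4, 32, 32)))
        with pytest.raises(ValueError):
            tissue_threshold(img, np.zeros(img.shape, bool))


class TestFoldChange:
    def test_uniform_image_unity_everywhere(self):
        img = _volume(np.full((4, 32, 32), 100.0))
        mask = cylinder_mask(6.0, shape=(4, 32, 32))
        tissue = np.ones(img.shape, bool)
        dist = ndimage.distance_transform_edt(~mask.voxels.astype(bool))
        dm = vesselmap.estimate_diameters(mask)
        comp = vesselmap.compartmentalize(dist, dm, 20.0, tissue)
        out = fold_change(
            img, np.ones(img.shape, bool), tissue, 100.0, compartments=comp
        )
        assert np.allclose(out["fold_change"], 1.0)

    def test_shell_at_twice_background(self):
        shape = (6, 41, 41)
        mask = cylinder_mask(6.0, shape=shape)
        lum = mask.voxels.astype(bool)
        dist = ndimage.distance_transform_edt(~lum)
        shell = (dist > 0) & (dist <= 8.0)
        img = np.full(shape, 100.0)
        img[shell] = 200.0
        img[lum] = 300.0
        tissue = np.ones(shape, bool)
        dm = vesselmap.estimate_diameters(mask)
        comp = vesselmap.compartmentalize(dist, dm, 40.0, tissue)
        out = fold_change(
            _volume(img), shell | lum, tissue, 100.0, compartments=comp
        )
        ivd25 = out.loc[
            (out["compartment"] == "IVD25") & (out["vessel_class"] == "all"),
            "fold_change",
        ].iloc[0]
        assert ivd25 == pytest.approx(2.0, abs=0.1)

    def test_empty_stratum_reports_unity_with_zero_voxels(self):
        shape = (4, 32, 32)
        mask = cylinder_mask(6.0, shape=shape)
        dist = ndimage.distance_transform_edt(~mask.voxels.astype(bool))
        dm = vesselmap.estimate_diameters(mask)
        tissue = np.ones(shape, bool)
        comp = vesselmap.compartmentalize(dist, dm, 20.0, tissue)
        out = fold_change(
            _volume(np.full(shape, 50.0)),
            np.zeros(shape, bool),
            tissue,
            50.0,
            compartments=comp,
        )
        assert np.allclose(out["fold_change"], 1.0)
        assert (out["n_voxels"] == 0).all()

    def test_nonpositive_background_rejected(self):
        img = _volume(np.ones((2, 8, 8)))
        with pytest.raises(ValueError):
            fold_change(img, np.ones(img.shape, bool), np.ones(img.shape, bool), 0.0)


class TestExtravasationDistance:
    def test_signal_equals_lumen_gives_zero(self):
        mask = cylinder_mask(6.0, shape=(6, 33, 33))
        lum = mask.voxels.astype(bool)
        res = extravasation_distance(
            lum, lum, np.ones(lum.shape, bool), (1, 1, 1)
        )
        assert res["mean_um"] == 0.0
        assert res["n"] == 0
        assert res["empty"]

    def test_shell_front_matches_euclidean_oracle(self):
        # convex obstacle-free tissue: geodesic = Euclidean within one
        # in-plane voxel
        shape = (6, 61, 61)
        mask = cylinder_mask(6.0, shape=shape)
        lum = mask.voxels.astype(bool)
        dist = ndimage.distance_transform_edt(~lum, sampling=(1, 1, 1))
        signal = lum | ((dist > 0) & (dist <= 10.0))
        tissue = np.ones(shape, bool)
        res = extravasation_distance(signal, lum, tissue, (1, 1, 1), mode="2d")
        euclid = dist[tuple(res["coords"].T)]
        assert abs(res["mean_um"] - euclid.mean()) <= 1.0

    def test_geodesic_respects_tissue_obstacles(self):
        # a wall between vessel and signal forces a detour: geodesic must
        # exceed the straight-line distance
        shape = (3, 41, 41)
        lum = np.zeros(shape, bool)
        lum[:, 20, 5] = True
        tissue = np.ones(shape, bool)
        tissue[:, 10:31, 12] = False  # wall with openings at top/bottom
        signal = np.zeros(shape, bool)
        signal[:, 20, 20] = True
        geo = drugmap.geodesic_distance_from_lumen(lum, tissue, (1, 1, 1), mode="2d")
        straight = ndimage.distance_transform_edt(~lum, sampling=(1, 1, 1))
        assert geo[1, 20, 20] > straight[1, 20, 20] + 5.0

    def test_monotone_recovery_across_extent_ladder(self):
        # sham -> repeated-treatment ladder of generative extents: the
        # measured distances must preserve the ordering
        shape = (10, 81, 81)
        spacing = (2.0, 1.0, 1.0)
        means = []
        for extent in (2.0, 9.0, 16.0, 21.0):
            preset = synthgen.TissuePreset(
                name="toy",
                diameter_mean_um=6.0,
                diameter_sd_um=0.5,
                intervessel_distance_um=60.0,
                background_level=100.0,
                enhancement_factor={("TTX1", "BVZ"): 2.0},
                extravasation_extent_um={("TTX1", "BVZ"): extent},
            )
            net = synthgen.generate_vessel_network(
                preset, (18, 80, 80), seed=1, calibrate=False
            )
            lumen = synthgen.rasterize_vessels(net, shape, spacing)
            img = synthgen.render_drug_channel(
                lumen, net, preset, "TTX1", "BVZ", seed=3, noise_sd=2.0
            )
            pre = preprocess_drug(img)
            thr, flat = tissue_threshold(pre, np.ones(shape, bool))
            sig = flat.voxels > thr.threshold_value
            res = extravasation_distance(
                sig, lumen.voxels.astype(bool), np.ones(shape, bool),
                spacing, cap_um=30.0,
            )
            means.append(res["mean_um"])
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_cap_enforces_measurement_ceiling(self):
        shape = (6, 61, 61)
        mask = cylinder_mask(4.0, shape=shape)
        lum = mask.voxels.astype(bool)
        dist = ndimage.distance_transform_edt(~lum)
        signal = lum | (dist <= 25.0)
        res = extravasation_distance(
            signal, lum, np.ones(shape, bool), (1, 1, 1), cap_um=12.0
        )
        assert res["distances_um"].max() <= 12.0

    def test_right_skewed_front_distances_on_preset_phantom(self):
        preset = synthgen.get_preset("GM")
        shape = (32, 121, 121)
        spacing = (2.0, 1.0, 1.0)
        net = synthgen.generate_vessel_network(
            preset, tuple((n - 1) * s for n, s in zip(shape, spacing)), seed=11
        )
        lumen = synthgen.rasterize_vessels(net, shape, spacing)
        img = synthgen.render_drug_channel(
            lumen, net, preset, "TTX1", "BVZ", seed=13
        )
        pre = preprocess_drug(img)
        thr, flat = tissue_threshold(pre, np.ones(shape, bool))
        sig = flat.voxels > thr.threshold_value
        res = extravasation_distance(
            sig, lumen.voxels.astype(bool), np.ones(shape, bool), spacing,
            cap_um=17.4,
        )
        h = distance_histogram(res["distances_um"])
        assert h["skewness"] > 0

    def test_no_lumen_raises(self):
        with pytest.raises(ValueError):
            extravasation_distance(
                np.ones((2, 8, 8), bool),
                np.zeros((2, 8, 8), bool),
                np.ones((2, 8, 8), bool),
                (1, 1, 1),
            )


class TestAttribution:
    def _two_vessel_setup(self):
        shape = (6, 41, 81)
        lum = np.zeros(shape, bool)
        yy, xx = np.meshgrid(np.arange(41), np.arange(81), indexing="ij")
        small = (yy - 20) ** 2 + (xx - 15) ** 2 <= 2.0**2  # d = 4: capillary
        big = (yy - 20) ** 2 + (xx - 60) ** 2 <= 6.0**2  # d = 12: major
        lum |= np.broadcast_to(small | big, shape)
        dm = vesselmap.estimate_diameters(
            ImageVolume(lum.astype(np.uint8), (1, 1, 1), "label")
        )
        return shape, lum, small, big, dm

    def test_single_capillary_takes_all_signal(self):
        mask = cylinder_mask(4.0, shape=(4, 33, 33))
        dm = vesselmap.estimate_diameters(mask)
        lum = mask.voxels.astype(bool)
        dist = ndimage.distance_transform_edt(~lum)
        sig = (dist > 0) & (dist <= 5.0)
        coords = np.argwhere(sig)
        out = attribute_to_vessel_class(coords, dist[sig], dm)
        cap = out.set_index("vessel_class")
        assert cap.loc["capillary", "n_voxels"] == sig.sum()
        assert cap.loc["microvessel", "n_voxels"] == 0

    def test_shell_on_major_vessel_only(self):
        shape, lum, small, big, dm = self._two_vessel_setup()
        dist_big = ndimage.distance_transform_edt(~np.broadcast_to(big, shape))
        sig = (dist_big > 0) & (dist_big <= 3.0) & ~lum
        coords = np.argwhere(sig)
        dist = ndimage.distance_transform_edt(~lum)
        out = attribute_to_vessel_class(coords, dist[sig], dm).set_index(
            "vessel_class"
        )
        assert out.loc["capillary", "n_voxels"] == 0
        assert out.loc["major", "n_voxels"] == sig.sum()

    def test_equidistant_voxel_resolves_to_lower_segment_id(self):
        # two identical one-voxel-wide vessels; the midpoint voxel ties
        shape = (1, 3, 9)
        lum = np.zeros(shape, bool)
        lum[0, 1, 1] = True
        lum[0, 1, 7] = True
        dm = vesselmap.estimate_diameters(
            ImageVolume(lum.astype(np.uint8), (1, 1, 1), "label")
        )
        assert len(dm.segments) == 2
        coords = np.array([[0, 1, 4]])
        out = attribute_to_vessel_class(coords, np.array([3.0]), dm)
        assigned = out.loc[out["n_voxels"] > 0]
        assert len(assigned) == 1
        # lower segment id is the first-labeled vessel
        lower_class = (
            vesselmap.classify_vessels(dm)
            .sort_values("segment_id")["vessel_class"]
            .iloc[0]
        )
        assert assigned["vessel_class"].iloc[0] == lower_class


class TestIntensityGradient:
    def test_arithmetic(self):
        quant = pd.DataFrame(
            {
                "compartment": ["intravascular", "IVD50"] * 2,
                "vessel_class": ["capillary"] * 2 + ["major"] * 2,
                "fold_change": [2.0, 1.5, 3.0, 3.0],
                "n_voxels": [10] * 4,
            }
        )
        out = intensity_gradient(quant).set_index("vessel_class")
        assert out.loc["capillary", "percent_decrease"] == pytest.approx(25.0)
        assert out.loc["major", "percent_decrease"] == pytest.approx(0.0)

    def test_missing_stratum_flagged_not_imputed(self):
        quant = pd.DataFrame(
            {
                "compartment": ["intravascular"],
                "vessel_class": ["capillary"],
                "fold_change": [2.0],
                "n_voxels": [5],
            }
        )
        out = intensity_gradient(quant)
        assert out["missing"].iloc[0]
        assert np.isnan(out["percent_decrease"].iloc[0])

    def test_linear_decay_profile_matches_analytic_integral(self):
        # single cylinder with a known linear profile; the IV-to-IVD50
        # signal decrease must match the continuum average of the profile
        shape = (6, 81, 81)
        mask = cylinder_mask(8.0, shape=shape)
        lum = mask.voxels.astype(bool)
        dist = ndimage.distance_transform_edt(~lum)
        bg, enh, extent = 100.0, 3.0, 20.0
        img = bg * (1 + (enh - 1) * np.clip(1 - dist / extent, 0, None))
        img[lum] = 2.0 * enh * bg
        tissue = np.ones(shape, bool)
        dm = vesselmap.estimate_diameters(mask)
        ivd = 40.0
        comp = vesselmap.compartmentalize(dist, dm, ivd, tissue)
        sig = img > bg * 1.05
        out = fold_change(_volume(img), sig, tissue, bg, compartments=comp)
        grad = intensity_gradient(
            out[out["vessel_class"] == "all"].assign(vessel_class="all")
        )
        got = grad["percent_decrease"].iloc[0]
        # continuum: annulus-weighted mean of the profile over the IVD50
        # band (10..19 um from the estimated 8 um vessel's surface)
        r = 4.0
        lo, hi = 0.25 * ivd, extent * 0.95
        dd = np.linspace(lo, hi, 2000)
        w = r + dd
        prof = bg * (1 + (enh - 1) * (1 - dd / extent))
        fc_band = np.trapezoid(prof * w, dd) / np.trapezoid(w, dd) / bg
        expected = (2 * enh - fc_band) / (2 * enh) * 100.0
        assert got == pytest.approx(expected, rel=0.10)
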