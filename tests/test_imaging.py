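"""Thresholding, illumination, segmentation and feature extraction."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

from squeezelab import ImageStack, synthgen
from squeezelab.imaging import (
    ConstantImageError,
    IlluminationModel,
    correct_illumination,
    derive_cytoplasm,
    estimate_illumination,
    extract_features,
    mce_threshold,
    segment_cells,
    segment_nuclei,
    segment_spheres,
)


def mce_oracle(img: np.ndarray) -> float:
    """Plain-loop exhaustive minimization of the cross-entropy objective
    over all 8-bit cut points; independent of the vectorized path."""
    counts = np.bincount(img.ravel(), minlength=256).astype(float)
    centers = np.arange(256) + 0.5
    best, best_k = np.inf, None
    for k in range(1, 256):
        m0b, m0a = counts[:k].sum(), counts[k:].sum()
        if m0b == 0 or m0a == 0:
            continue
        m1b = float((counts[:k] * centers[:k]).sum())
        m1a = float((counts[k:] * centers[k:]).sum())
        eta = 0.0
        if m1b > 0:
            eta -= m1b * np.log(m1b / m0b)
        if m1a > 0:
            eta -= m1a * np.log(m1a / m0a)
        if eta < best - 1e-12:
            best, best_k = eta, k
    return float(best_k)


class TestMceThreshold:
    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        for _ in range(50):
            img = (
                np.concatenate(
                    [
                        rng.normal(rng.uniform(20, 90), rng.uniform(5, 25), 500),
                        rng.normal(rng.uniform(120, 230), rng.uniform(5, 30), 400),
                    ]
                )
                .clip(0, 255)
                .astype(np.uint8)
                .reshape(30, 30)
            )
            assert mce_threshold(img) == mce_oracle(img)

    def test_bimodal_threshold_separates_modes(self):
        img = np.array([10] * 64 + [200] * 64, dtype=np.uint8).reshape(8, 16)
        thr = mce_threshold(img)
        assert 10 < thr < 200

    def test_constant_image_raises(self):
        with pytest.raises(ConstantImageError):
            mce_threshold(np.full((8, 8), 7, dtype=np.uint8))


class TestIllumination:
    def test_uniform_illumination_recovers_flat_field(self, rng):
        frames = np.zeros((10, 96, 96))
        for f in frames:
            for _ in range(6):
                rr, cc = draw_disk(
                    (rng.uniform(12, 84), rng.uniform(12, 84)), 7, shape=(96, 96)
                )
                f[rr, cc] = 500.0
        stack = ImageStack(frames[:, None], pixel_size=1.0, channel_names=("c",))
        model = estimate_illumination(stack)["c"]
        assert np.abs(model.flatfield - 1.0).max() < 0.01

    def test_recovers_injected_corner_vignetting(self):
        spec = synthgen.PlateSpec(n_wells=24, seed=5, flatfield_corner_factor=0.5)
        wells, _ = synthgen.generate_if_plate(spec)
        ens = np.concatenate([ws.data for ws in wells.values()], axis=0)
        stack = ImageStack(
            ens, pixel_size=spec.pixel_size, channel_names=spec.channel_names
        )
        models = estimate_illumination(stack)
        c = spec.image_size // 2
        for ch in spec.channel_names:
            flat = models[ch].flatfield
            assert flat[0, 0] / flat[c, c] == pytest.approx(0.5, rel=0.05)
            assert flat.mean() == pytest.approx(1.0, abs=1e-9)

    def test_pure_darkfield_estimated(self, rng):
        frames = rng.normal(10.0, 0.5, (12, 64, 64))
        stack = ImageStack(frames[:, None], pixel_size=1.0, channel_names=("c",))
        model = estimate_illumination(stack)["c"]
        assert model.darkfield.mean() == pytest.approx(10.0, rel=0.02)

    def test_all_zero_channel_returns_identity_with_warning(self):
        stack = ImageStack(
            np.zeros((9, 1, 32, 32)), pixel_size=1.0, channel_names=("c",)
        )
        with pytest.warns(UserWarning, match="all zero"):
            model = estimate_illumination(stack)["c"]
        assert np.all(model.flatfield == 1.0) and np.all(model.darkfield == 0.0)

    def test_single_frame_warns(self, rng):
        frames = rng.uniform(0, 100, (1, 32, 32))
        stack = ImageStack(frames[:, None], pixel_size=1.0, channel_names=("c",))
        with pytest.warns(UserWarning, match="frame"):
            estimate_illumination(stack)

    def test_exact_inversion_of_known_model(self, rng):
        truth = rng.uniform(0, 200, (3, 1, 40, 40))
        flat = synthgen.make_flatfield((40, 40), 0.6)
        dark = np.full((40, 40), 12.0)
        observed = ImageStack(
            truth * flat + dark, pixel_size=1.0, channel_names=("c",)
        )
        model = IlluminationModel(flatfield=flat, darkfield=dark)
        corrected = correct_illumination(observed, {"c": model})
        assert np.allclose(corrected.data, truth)
        assert corrected.metadata["illumination_corrected"]

    def test_identity_model_is_a_no_op_and_clamp_counts(self):
        data = np.arange(16.0).reshape(1, 1, 4, 4)
        stack = ImageStack(data, pixel_size=1.0, channel_names=("c",))
        ident = IlluminationModel.identity((4, 4))
        assert np.array_equal(correct_illumination(stack, {"c": ident}).data, data)
        heavy = IlluminationModel(np.ones((4, 4)), np.full((4, 4), 100.0))
        corrected = correct_illumination(stack, {"c": heavy})
        assert corrected.metadata["clamped_pixels"]["c"] == 16
        assert corrected.data.min() == 0.0

    def test_shape_mismatch_rejected(self):
        stack = ImageStack(np.ones((1, 1, 4, 4)), pixel_size=1.0, channel_names=("c",))
        with pytest.raises(ValueError, match="shape"):
            correct_illumination(stack, {"c": IlluminationModel.identity((8, 8))})


def _disk_image(centres, radius=8, size=96, value=200.0):
    img = np.zeros((size, size))
    for cy, cx in centres:
        rr, cc = draw_disk((cy, cx), radius, shape=img.shape)
        img[rr, cc] = value
    return img


class TestSegmentation:
    def test_two_disks_two_labels_with_accurate_centroids(self):
        centres = [(30.0, 30.0), (65.0, 62.0)]
        mask = segment_nuclei(_disk_image(centres), pixel_size=1.0)
        assert mask.n_labels == 2
        feats = extract_features(
            mask, mask, derive_cytoplasm(mask, mask), {}, exclude_border=False
        )
        found = sorted(zip(feats.centroid_y_um, feats.centroid_x_um))
        for (fy, fx), (ty, tx) in zip(found, sorted(centres)):
            assert abs(fy - ty) <= 1.0 and abs(fx - tx) <= 1.0

    def test_blank_image_gives_zero_labels(self):
        assert segment_nuclei(np.zeros((32, 32)), pixel_size=1.0).n_labels == 0

    def test_touching_disks_split_by_watershed(self):
        img = _disk_image([(40.0, 35.0), (40.0, 55.0)], radius=12)
        merged = segment_nuclei(img, pixel_size=1.0, split_touching=False)
        assert merged.n_labels == 1
        split = segment_nuclei(
            img, pixel_size=1.0, split_touching=True, min_seed_distance_um=10.0
        )
        assert split.n_labels == 2

    def test_cells_partition_foreground_and_keep_their_seed(self):
        body = _disk_image([(30.0, 30.0), (60.0, 60.0)], radius=14, value=120.0)
        dapi = _disk_image([(30.0, 30.0), (60.0, 60.0)], radius=5)
        nuclei = segment_nuclei(dapi, pixel_size=1.0)
        cells = segment_cells(body, nuclei)
        assert cells.n_labels == 2
        fg = cells.data > 0
        assert np.all(fg[body > 60])  # foreground fully assigned
        for lab in nuclei.labels:
            owner = np.unique(cells.data[nuclei.data == lab])
            assert list(owner) == [lab]  # each nucleus inside exactly its cell

    def test_zero_seeds_zero_cells(self):
        body = _disk_image([(30.0, 30.0)])
        empty = segment_nuclei(np.zeros((96, 96)), pixel_size=1.0)
        assert segment_cells(body, empty).n_labels == 0

    def test_nucleus_outside_foreground_flagged(self):
        body = np.zeros((64, 64))
        dapi = _disk_image([(32.0, 32.0)], radius=5, size=64)
        nuclei = segment_nuclei(dapi, pixel_size=1.0)
        cells = segment_cells(body, nuclei)
        assert 1 in cells.flags
        assert cells.area(1) == nuclei.area(1)

    def test_cytoplasm_is_exact_set_difference(self, small_plate):
        spec, wells, _ = small_plate
        ws = wells[0]
        nuclei = segment_nuclei(ws.data[0, 0].astype(float), spec.pixel_size)
        cells = segment_cells(ws.data[0, 1].astype(float), nuclei)
        cyto = derive_cytoplasm(cells, nuclei)
        for lab in cells.labels:
            cell_px = set(map(tuple, np.argwhere(cells.data == lab)))
            nuc_px = set(map(tuple, np.argwhere(nuclei.data == lab)))
            cyto_px = set(map(tuple, np.argwhere(cyto.data == lab)))
            assert cyto_px == cell_px - nuc_px  # pixelwise set-difference oracle
            assert len(cell_px) == len(nuc_px) + len(cyto_px)

    def test_nucleus_filling_cell_yields_empty_flagged_cytoplasm(self):
        dapi = _disk_image([(32.0, 32.0)], radius=10, size=64)
        nuclei = segment_nuclei(dapi, pixel_size=1.0)
        cyto = derive_cytoplasm(nuclei, nuclei)
        assert cyto.n_labels == 0 and 1 in cyto.flags


class TestSpheres:
    def test_disk_area_within_two_percent(self):
        img = np.full((160, 160), 200.0)
        rr, cc = draw_disk((80, 80), 50, shape=img.shape)
        img[rr, cc] = 60.0
        _, areas = segment_spheres(img, pixel_size=1.0)
        assert len(areas) == 1
        assert areas.area_um2.iloc[0] == pytest.approx(np.pi * 50**2, rel=0.02)

    def test_blank_field_no_spheres(self):
        _, areas = segment_spheres(np.full((64, 64), 100.0), pixel_size=1.0)
        assert areas.empty

    def test_two_disks_ordered_areas(self):
        img = np.full((200, 200), 200.0)
        for c, r in (((60, 60), 20), ((140, 140), 35)):
            rr, cc = draw_disk(c, r, shape=img.shape)
            img[rr, cc] = 60.0
        mask, areas = segment_spheres(img, pixel_size=1.0)
        assert mask.n_labels == 2
        big, small = areas.area_um2.max(), areas.area_um2.min()
        assert big / small == pytest.approx((35 / 20) ** 2, rel=0.05)


class TestFeatures:
    @staticmethod
    def _ellipse_mask(a=20, b=10, size=96):
        yy, xx = np.mgrid[0:size, 0:size]
        m = ((yy - size / 2) / b) ** 2 + ((xx - size / 2) / a) ** 2 <= 1.0
        from squeezelab import LabelMask

        return LabelMask(m.astype(np.int32), pixel_size=1.0)

    def test_moment_ellipse_axes_match_geometry(self):
        mask = self._ellipse_mask(a=20, b=10)
        feats = extract_features(
            mask, mask, derive_cytoplasm(mask, mask), {}, exclude_border=False
        )
        assert feats.major_axis_um.iloc[0] == pytest.approx(40.0, abs=1.0)
        assert feats.minor_axis_um.iloc[0] == pytest.approx(20.0, abs=1.0)

    def test_uniform_intensity_mean_and_integral(self):
        mask = self._ellipse_mask()
        img = np.where(mask.data > 0, 7.0, 0.0)
        feats = extract_features(
            mask, mask, derive_cytoplasm(mask, mask), {"c": img}, exclude_border=False
        )
        assert feats.cell_mean_c.iloc[0] == pytest.approx(7.0)
        assert feats.cell_int_c.iloc[0] == pytest.approx(7.0 * feats.area_um2.iloc[0])

    def test_circle_has_near_zero_eccentricity(self):
        mask = self._ellipse_mask(a=15, b=15)
        feats = extract_features(
            mask, mask, derive_cytoplasm(mask, mask), {}, exclude_border=False
        )
        assert feats.eccentricity.iloc[0] < 0.05
        assert feats.major_axis_um.iloc[0] == pytest.approx(
            feats.minor_axis_um.iloc[0], rel=0.01
        )

    def test_translation_and_rotation_invariance(self, rng):
        from squeezelab import LabelMask

        base = np.zeros((80, 80), dtype=np.int32)
        yy, xx = np.mgrid[0:80, 0:80]
        base[((yy - 30) / 8) ** 2 + ((xx - 30) / 16) ** 2 <= 1.0] = 1
        img = rng.uniform(50, 150, (80, 80))

        def measure(mask_arr, image):
            m = LabelMask(mask_arr.astype(np.int32), pixel_size=1.0)
            return extract_features(
                m, m, derive_cytoplasm(m, m), {"c": image}, exclude_border=False
            ).iloc[0]

        ref = measure(base, img)
        shifted = measure(np.roll(base, (11, 7), axis=(0, 1)),
                          np.roll(img, (11, 7), axis=(0, 1)))
        rotated = measure(np.rot90(base), np.rot90(img))
        for other in (shifted, rotated):
            for col in ("area_um2", "major_axis_um", "minor_axis_um", "cell_mean_c"):
                assert other[col] == pytest.approx(ref[col], rel=0.01)

    def test_border_cells_flagged_and_dropped_by_default(self):
        from squeezelab import LabelMask

        arr = np.zeros((40, 40), dtype=np.int32)
        arr[0:10, 0:10] = 1  # touches border
        arr[20:30, 20:30] = 2
        mask = LabelMask(arr, pixel_size=1.0)
        cyto = derive_cytoplasm(mask, mask)
        kept = extract_features(mask, mask, cyto, {})
        assert list(kept.label) == [2]
        full = extract_features(mask, mask, cyto, {}, exclude_border=False)
        assert full.set_index("label").qc_border.to_dict() == {1: True, 2: False}
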