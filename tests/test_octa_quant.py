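"""Vessel segmentation and the six vessel parameters."""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi

from octapipe.octa_quant import (
    DEFAULT_SCALES_PX,
    FlowImage,
    QCError,
    VesselMaps,
    binarize,
    compute_metrics,
    enhance_vessels,
    load_flow_image,
    local_metric_map,
    perimeter_map,
    qc_filter,
    quantify_image,
    remove_large_vessels,
    segment_vessels,
    skeletonize,
)
from octapipe.roi_geometry import (
    DISC_ANNULUS,
    MACULA_ANNULUS,
    ImageGrid,
    SectorPartition,
)
from octapipe.synthetic_data import write_phantom

from conftest import dice


def flow(arr, ssi=9.0, target="disc"):
    arr = np.asarray(arr, dtype=float)
    grid = ImageGrid(*arr.shape, extent_mm=3.0)
    return FlowImage(arr, grid, signal_strength_index=ssi, target=target)


def bar_image(shape=(64, 64), width=3, value=0.9):
    img = np.zeros(shape)
    r = shape[0] // 2
    img[r : r + width, 8 : shape[1] - 8] = value
    return img


class TestQC:
    @pytest.mark.parametrize("ssi,passes", [(8.0, True), (7.0, False), (6.5, False)])
    def test_strict_ssi_threshold(self, ssi, passes):
        assert qc_filter(flow(np.zeros((8, 8)), ssi=ssi)) is passes

    def test_missing_ssi_is_qc_error(self):
        with pytest.raises(QCError):
            qc_filter(flow(np.zeros((8, 8)), ssi=None))


class TestEnhancement:
    def test_constant_image_gives_constant_zero_vesselness_output(self):
        out = enhance_vessels(np.full((32, 32), 0.4))
        assert np.unique(out).size == 1
        assert np.unique(enhance_vessels(np.full((32, 32), 0.4),
                                         vesselness_weight=1.0)) == [0.0]

    def test_bar_response_dominates_background(self):
        img = bar_image()
        out = enhance_vessels(img)
        centerline = out[33, 10:54].mean()
        background = out[5:25, 5:60].mean()
        assert centerline >= 10 * max(background, 1e-12)

    def test_commutes_with_quarter_rotation(self):
        img = bar_image() + 0.05
        a = np.rot90(enhance_vessels(img))
        b = enhance_vessels(np.rot90(img))
        assert np.abs(a - b).max() < 1e-8

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError):
            enhance_vessels(np.zeros((8, 8)), scales_px=[])


class TestBinarize:
    def test_otsu_splits_bimodal_image(self):
        img = np.full((20, 20), 0.1)
        img[5:15, 5:15] = 0.9
        assert (binarize(img, "global_otsu") == (img == 0.9)).all()

    def test_fixed_level_recovers_bar_mask(self):
        img = bar_image()
        enhanced = enhance_vessels(img)
        mask = binarize(enhanced, "fixed", 0.5)
        assert dice(mask, img > 0) >= 0.95

    def test_all_zero_image_gives_empty_mask(self):
        assert not binarize(np.zeros((16, 16))).any()

    def test_fixed_without_level_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((8, 8)), "fixed")

    def test_raising_fixed_level_never_increases_vad(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        levels = np.sort(rng.random(10))
        vads = [binarize(img, "fixed", lv).mean() for lv in levels]
        assert all(b <= a for a, b in zip(vads, vads[1:]))


class TestLargeVesselRemoval:
    def test_trunk_removed_branches_retained(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[44:56, :] = True  # 12 px trunk
        for c in range(5, 100, 12):  # 2 px branches
            mask[10:44, c : c + 2] = True
            mask[56:90, c : c + 2] = True
        cap, large = remove_large_vessels(mask, diameter_cutoff_px=6)
        trunk = np.zeros_like(mask)
        trunk[44:56, :] = True
        branches_clear = mask & ~ndi.binary_dilation(trunk, iterations=4)
        assert (large & trunk).sum() / trunk.sum() >= 0.99
        assert (cap & branches_clear).sum() / branches_clear.sum() >= 0.99

    def test_thin_lines_yield_no_large_vessels(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10, :] = True
        mask[:, 30] = True
        for cutoff in (2, 4, 8):
            cap, large = remove_large_vessels(mask, cutoff)
            assert not large.any() and (cap == mask).all()

    def test_union_and_disjointness_on_random_masks(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            mask = ndi.binary_dilation(rng.random((60, 60)) > 0.9)
            cap, large = remove_large_vessels(mask, 5)
            assert not (cap & large).any()
            assert ((cap | large) == mask).all()

    def test_cutoff_below_one_rejected(self):
        with pytest.raises(ValueError):
            remove_large_vessels(np.zeros((8, 8), bool), 0)


class TestSkeleton:
    def test_bar_skeleton_length(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:13, 10:50] = True  # 3 px wide, 40 long
        assert abs(int(skeletonize(mask).sum()) - 40) <= 2

    def test_single_pixel_line_unchanged(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5, 3:27] = True
        assert (skeletonize(mask) == mask).all()

    def test_filled_disc_collapses_to_central_cluster(self):
        yy, xx = np.mgrid[0:60, 0:60]
        disc = (xx - 30) ** 2 + (yy - 30) ** 2 <= 15**2
        sk = skeletonize(disc)
        eight = np.ones((3, 3))
        assert ndi.label(sk, eight)[1] == ndi.label(disc, eight)[1]
        assert sk.sum() <= 0.05 * disc.sum()

    def test_phantom_skeleton_is_one_pixel_wide_and_preserves_components(
        self, clean_phantom
    ):
        mask = clean_phantom.truth.vessel_mask
        sk = skeletonize(mask)
        assert not (sk & ~mask).any()
        blocks = sliding_window_view(sk, (2, 2)).all(axis=(2, 3))
        assert not blocks.any()  # nowhere two pixels thick
        eight = np.ones((3, 3))
        assert ndi.label(sk, eight)[1] == ndi.label(mask, eight)[1]


class TestPerimeter:
    def test_one_pixel_line_is_all_perimeter(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[4, 2:18] = True
        assert (perimeter_map(mask) == mask).all()

    def test_filled_square_perimeter_count(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        assert perimeter_map(mask).sum() == 36

    def test_empty_mask(self):
        assert not perimeter_map(np.zeros((8, 8), bool)).any()


def maps_from_mask(mask):
    return VesselMaps(
        vessel_mask=mask,
        large_vessel_mask=np.zeros_like(mask),
        skeleton=skeletonize(mask),
        perimeter=perimeter_map(mask),
    )


class TestMetrics:
    def test_saturated_roi(self):
        mask = np.ones((32, 32), dtype=bool)
        m = compute_metrics(maps_from_mask(mask), np.full((32, 32), 0.5), mask)
        assert m.vad == 1.0 and m.flux == pytest.approx(0.5)

    def test_bar_vdi_matches_width(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:33, 8:56] = True
        m = compute_metrics(maps_from_mask(mask), np.zeros((64, 64)),
                            np.ones((64, 64), bool))
        assert 2.5 <= m.vdi <= 3.5

    def test_disc_vci_near_isoperimetric_limit(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (xx - 32) ** 2 + (yy - 32) ** 2 <= 20**2
        m = compute_metrics(maps_from_mask(disc), np.zeros((64, 64)),
                            np.ones((64, 64), bool))
        assert 0.8 <= m.vci <= 1.3

    def test_empty_roi_rejected(self):
        mask = np.zeros((16, 16), dtype=bool)
        with pytest.raises(ValueError):
            compute_metrics(maps_from_mask(mask), np.zeros((16, 16)), mask)

    def test_vessel_free_roi_flagged_undefined(self):
        maps = maps_from_mask(np.zeros((16, 16), dtype=bool))
        m = compute_metrics(maps, np.zeros((16, 16)), np.ones((16, 16), bool))
        assert m.vad == 0 and m.undefined and np.isnan(m.vdi) and np.isnan(m.vci)

    def test_skeleton_and_perimeter_densities_bounded_by_vad(self, noisy_phantom):
        maps = segment_vessels(noisy_phantom.image)
        roi = np.ones(maps.vessel_mask.shape, dtype=bool)
        m = compute_metrics(maps, noisy_phantom.image, roi)
        assert m.vsd <= m.vad and m.vpi <= m.vad

    def test_parallel_bar_grid_recovery_at_512(self):
        n, width, pitch = 512, 3, 16
        mask = np.zeros((n, n), dtype=bool)
        for c in range(0, n, pitch):
            mask[:, c : c + width] = True
        m = compute_metrics(maps_from_mask(mask), np.zeros((n, n)),
                            np.ones((n, n), bool))
        assert m.vad == pytest.approx(width / pitch, rel=0.10)
        assert m.vsd == pytest.approx(1 / pitch, rel=0.10)
        assert m.vdi == pytest.approx(width, rel=0.10)

    def test_metrics_invariant_under_rotations_and_flips(self, clean_phantom):
        img = clean_phantom.image
        ref = None
        for transform in (lambda a: a, np.rot90, np.flipud, np.fliplr):
            arr = transform(img.intensities).copy()
            fi = flow(arr)
            maps = segment_vessels(fi)
            m = compute_metrics(maps, fi, np.ones(arr.shape, bool))
            vals = np.array([m.vad, m.vsd, m.vdi, m.vpi, m.vci, m.flux])
            if ref is None:
                ref = vals
            else:
                assert np.allclose(vals, ref, rtol=0.02)


class TestQuantifyImage:
    def test_disc_row_contract(self, noisy_phantom):
        rows = quantify_image(
            noisy_phantom.image,
            [(DISC_ANNULUS, SectorPartition("quadrants_4", "OD"))],
        )
        assert [r.region_label for r in rows] == ["whole", "S", "N", "I", "T"]

    def test_macula_row_contract(self, noisy_phantom):
        rows = quantify_image(
            noisy_phantom.image,
            [(MACULA_ANNULUS, SectorPartition("macula_6", "OD"))],
        )
        assert len(rows) == 7

    def test_deterministic(self, noisy_phantom):
        args = [(DISC_ANNULUS, SectorPartition("quadrants_4", "OD"))]
        a = quantify_image(noisy_phantom.image, args)
        b = quantify_image(noisy_phantom.image, args)
        assert a == b

    def test_low_ssi_image_rejected(self):
        img = flow(np.zeros((32, 32)), ssi=6.0)
        with pytest.raises(QCError):
            quantify_image(img, [])


class TestIOAndHeatmaps:
    def test_phantom_tiff_roundtrip(self, tmp_path, clean_phantom):
        paths = write_phantom(clean_phantom, tmp_path)
        loaded = load_flow_image(paths["image"])
        assert loaded.grid.shape == clean_phantom.image.grid.shape
        assert loaded.signal_strength_index == 9.0
        assert np.abs(
            loaded.intensities - clean_phantom.image.intensities
        ).max() < 1e-3

    def test_missing_sidecar_raises(self, tmp_path):
        import tifffile

        p = tmp_path / "orphan.tiff"
        tifffile.imwrite(p, np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(FileNotFoundError):
            load_flow_image(p)

    def test_local_vad_map_tracks_density(self, clean_phantom):
        maps = clean_phantom.truth
        lv = local_metric_map(maps, "vad", 31)
        assert lv.min() >= 0 and lv.max() <= 1
        assert lv.mean() == pytest.approx(maps.vessel_mask.mean(), rel=0.15)
        with pytest.raises(ValueError):
            local_metric_map(maps, "vad", 10)
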