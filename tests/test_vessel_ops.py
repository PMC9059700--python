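"""Vessel mask cleanup, segmentation backends, and inpainting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fundoprep import (SynthSpec, VesselMask, clean_mask, generate_fundus,
                       inpaint_vessels, segment_vessels)


def _flood_fill_components(binary, connectivity=8):
    """Brute-force component enumeration by explicit flood fill."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], []
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dr, dc in nbrs:
                        ny, nx = y + dr, x + dc
                        if (0 <= ny < h and 0 <= nx < w and binary[ny, nx]
                                and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


def _oracle_clean(raster, thr=20, min_px=100, connectivity=8):
    out = raster.copy()
    out[out < thr] = 0
    for comp in _flood_fill_components(out > 0, connectivity):
        if len(comp) < min_px:
            for y, x in comp:
                out[y, x] = 0
    return out


class TestCleanMask:
    def test_99_pixel_component_removed(self):
        m = np.zeros((20, 200), np.uint8)
        m[5, :99] = 200
        assert clean_mask(VesselMask(m)).raster.max() == 0

    def test_100_pixel_component_survives(self):
        m = np.zeros((20, 200), np.uint8)
        m[5, :100] = 200
        assert np.array_equal(clean_mask(VesselMask(m)).raster, m)

    def test_subthreshold_intensity_removed(self):
        m = np.full((20, 20), 19, np.uint8)
        assert clean_mask(VesselMask(m)).raster.max() == 0

    def test_threshold_boundary_survives_when_component_big_enough(self):
        m = np.zeros((20, 200), np.uint8)
        m[5:7, :60] = 20  # intensity exactly 20, 120 px
        assert np.array_equal(clean_mask(VesselMask(m)).raster, m)

    def test_threshold_splits_component_before_size_filter(self):
        # a 150-px run whose middle 60 px are sub-threshold: the remaining
        # halves are 45 px each and both fall to the size filter
        m = np.zeros((10, 200), np.uint8)
        m[5, :150] = 200
        m[5, 45:105] = 10
        assert clean_mask(VesselMask(m)).raster.max() == 0

    def test_idempotent_and_monotone(self, rng):
        m = (rng.uniform(0, 255, (64, 64)) *
             (rng.uniform(size=(64, 64)) < 0.4)).astype(np.uint8)
        once = clean_mask(VesselMask(m))
        twice = clean_mask(once)
        assert np.array_equal(once.raster, twice.raster)
        assert ((once.raster > 0) <= (m > 0)).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           connectivity=st.sampled_from([4, 8]))
    def test_matches_flood_fill_oracle(self, seed, connectivity):
        r = np.random.default_rng(seed)
        m = (r.uniform(0, 255, (24, 24)) *
             (r.uniform(size=(24, 24)) < 0.55)).astype(np.uint8)
        got = clean_mask(VesselMask(m, connectivity=connectivity),
                         min_component_px=12)
        want = _oracle_clean(m, min_px=12, connectivity=connectivity)
        assert np.array_equal(got.raster, want)


class TestSegmentVessels:
    def test_identity_backend_returns_stored_mask(self, diseased_phantom):
        img, gt = diseased_phantom
        stored = (gt.vessel_mask * 255).astype(np.uint8)
        out = segment_vessels(img, backend=lambda px: stored)
        assert np.array_equal(out.raster, stored)

    def test_naive_backend_recall_on_wide_vessels(self, diseased_phantom):
        from scipy import ndimage

        img, gt = diseased_phantom
        mask = clean_mask(segment_vessels(img))
        core = ndimage.binary_erosion(gt.vessel_mask, np.ones((2, 2)))
        assert core.any()
        recall = (mask.binary & core).sum() / core.sum()
        assert recall >= 0.5

    def test_all_black_image_gives_empty_mask(self):
        out = segment_vessels(np.zeros((64, 64, 3), np.uint8))
        assert not out.binary.any()

    def test_shape_mismatch_rejected(self, centered_phantom):
        with pytest.raises(ValueError):
            segment_vessels(centered_phantom[0],
                            backend=lambda px: np.zeros((8, 8), np.uint8))


class TestInpaintVessels:
    def test_empty_mask_is_identity(self, centered_phantom):
        img = centered_phantom[0]
        out = inpaint_vessels(img, VesselMask(np.zeros((256, 256), np.uint8)))
        assert np.array_equal(out.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        im = np.full((40, 40, 3), 77, np.uint8)
        m = np.zeros((40, 40), np.uint8)
        m[10:20, 10:20] = 255
        out = inpaint_vessels(im, VesselMask(m))
        assert (out.pixels == 77).all()

    def test_touches_only_masked_pixels(self, diseased_phantom):
        img, gt = diseased_phantom
        m = VesselMask((gt.vessel_mask * 255).astype(np.uint8))
        out = inpaint_vessels(img, m)
        assert np.array_equal(out.pixels[~gt.vessel_mask],
                              img.pixels[~gt.vessel_mask])

    def test_moves_masked_pixels_toward_vessel_free_twin(self):
        img, gt = generate_fundus(SynthSpec(seed=17))
        m = gt.vessel_mask
        out = inpaint_vessels(img, VesselMask((m * 255).astype(np.uint8)))
        err_before = np.abs(img.pixels[m].astype(float)
                            - gt.vessel_free[m]).mean()
        err_after = np.abs(out.pixels[m].astype(float)
                           - gt.vessel_free[m]).mean()
        assert err_after < err_before

    def test_full_mask_rejected(self, centered_phantom):
        full = VesselMask(np.full((256, 256), 255, np.uint8))
        with pytest.raises(ValueError):
            inpaint_vessels(centered_phantom[0], full)
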