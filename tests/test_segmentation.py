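"""Nuclear detection, cytoplasm ring expansion and per-cell statistics."""

import numpy as np
import pandas as pd
import pytest

from mifquant import (
    ComponentStack,
    LabelImage,
    compute_cell_stats,
    expand_cytoplasm,
    ring_width_px,
    segment_nuclei,
    unmix_pixelwise,
)
from mifquant.exceptions import InvalidParameterError
from mifquant.segment import centroids
from mifquant.synth_images import (
    match_to_truth,
    place_random_cells,
    render_tissue_image,
    truth_label_image,
)
from tests.conftest import PIXEL_SIZE


def _disk_labels(shape, centers, radius_px, pixel_size=PIXEL_SIZE):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    labels = np.zeros(shape, dtype=np.int32)
    for k, (r0, c0) in enumerate(centers, start=1):
        labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2] = k
    return LabelImage(labels, pixel_size)


class TestSegmentNuclei:
    def test_blank_plane_yields_zero_cells(self):
        out = segment_nuclei(np.zeros((64, 64)), PIXEL_SIZE)
        assert out.n_cells == 0

    def test_noiseless_render_recovers_all_cells_and_centroids(self, library):
        shape = (320, 320)
        cells = place_random_cells(50, shape, PIXEL_SIZE, seed=21)
        image, truth = render_tissue_image(cells, library, shape, PIXEL_SIZE,
                                           noise_sd=0.0, seed=22)
        dapi = unmix_pixelwise(image, library).plane("DAPI")
        nuclei = segment_nuclei(dapi, PIXEL_SIZE)
        assert nuclei.n_cells == 50
        cent = centroids(nuclei)
        true_cent = truth[["centroid_row", "centroid_col"]].to_numpy()
        detected = pd.DataFrame(cent, columns=["centroid_row", "centroid_col"])
        idx = match_to_truth(detected, truth)
        assert sorted(idx) == list(range(50))  # bijective matching
        dists = np.hypot(*(cent - true_cent[idx]).T)
        assert dists.max() < 1.0

    def test_fused_dumbbell_is_split_into_two(self):
        # two overlapping disks form one connected blob; watershed must split it
        shape = (64, 64)
        r = 8
        plane = np.zeros(shape)
        for r0, c0 in ((32, 24), (32, 38)):
            rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
            plane[(rr - r0) ** 2 + (cc - c0) ** 2 <= r**2] = 1.0
        nuclei = segment_nuclei(plane, PIXEL_SIZE)
        assert nuclei.n_cells == 2

    def test_min_area_filter_removes_debris(self):
        plane = np.zeros((64, 64))
        plane[10:12, 10:12] = 1.0  # 4 px = ~1 um^2 at 0.496 um/px
        rr, cc = np.mgrid[0:64, 0:64]
        plane[(rr - 40) ** 2 + (cc - 40) ** 2 <= 8**2] = 1.0
        nuclei = segment_nuclei(plane, PIXEL_SIZE, min_area_um2=7.0,
                                threshold_method="fixed", fixed_threshold=0.5)
        assert nuclei.n_cells == 1


class TestExpandCytoplasm:
    def test_two_um_at_paper_pixel_size_gives_four_pixel_ring(self):
        assert ring_width_px(2.0, 0.496) == 4

    def test_ring_width_along_axis(self):
        nuclei = _disk_labels((64, 64), [(32, 32)], radius_px=8)
        rings = expand_cytoplasm(nuclei, 2.0)
        row = rings.labels[32]
        left = np.flatnonzero(row == 1)
        assert len(left) == 8  # 4 px on each side along the central row

    def test_ring_area_matches_brute_force_annulus_count(self):
        r = 8
        nuclei = _disk_labels((64, 64), [(32, 32)], radius_px=r)
        rings = expand_cytoplasm(nuclei, 2.0)
        ring_px = int((rings.labels == 1).sum())
        # brute force: pixels within Euclidean distance 4 of the disk, minus the disk
        rr, cc = np.mgrid[0:64, 0:64]
        d2 = (rr - 32) ** 2 + (cc - 32) ** 2
        disk = d2 <= r**2
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~disk)
        annulus = int(((dist <= 4) & ~disk).sum())
        assert ring_px == annulus
        # and close to the continuum annulus area pi((r+4)^2 - r^2)
        assert abs(ring_px - np.pi * ((r + 4) ** 2 - r**2)) / ring_px < 0.15

    def test_adjacent_rings_partition_without_overlap(self):
        nuclei = _disk_labels((64, 96), [(32, 30), (32, 49)], radius_px=8)
        rings = expand_cytoplasm(nuclei, 2.0)
        # every ring pixel belongs to exactly one cell and never to a nucleus
        assert not np.any((rings.labels > 0) & (nuclei.labels > 0))
        assert set(np.unique(rings.labels)) == {0, 1, 2}

    def test_non_positive_expansion_is_invalid(self):
        nuclei = _disk_labels((32, 32), [(16, 16)], radius_px=5)
        with pytest.raises(InvalidParameterError):
            expand_cytoplasm(nuclei, 0.0)


class TestComputeCellStats:
    def _stack(self, planes):
        return ComponentStack(np.asarray(planes, dtype=float), PIXEL_SIZE,
                              [f"c{i}" for i in range(len(planes))])

    def test_constant_plane_gives_degenerate_stats(self):
        nuclei = _disk_labels((64, 64), [(20, 20), (44, 44)], radius_px=6)
        rings = expand_cytoplasm(nuclei, 2.0)
        stack = self._stack([np.full((64, 64), 7.5)])
        out = compute_cell_stats(stack, nuclei, rings)
        for comp in ("nucleus", "ring"):
            np.testing.assert_allclose(out[f"c0_{comp}_mean"], 7.5)
            np.testing.assert_allclose(out[f"c0_{comp}_min"], 7.5)
            np.testing.assert_allclose(out[f"c0_{comp}_max"], 7.5)
            np.testing.assert_allclose(out[f"c0_{comp}_sd"], 0.0, atol=1e-12)

    def test_ring_mean_equals_rendered_abundance(self, library, noiseless_scene):
        # noiseless input: skip the denoising blur so the recovered mask is
        # pixel-exact and the ring mean matches the rendered abundance exactly
        cells, image, truth = noiseless_scene
        stack = unmix_pixelwise(image, library)
        nuclei = segment_nuclei(stack.plane("DAPI"), PIXEL_SIZE, smooth_sigma_px=0.0)
        rings = expand_cytoplasm(nuclei, 2.0)
        stats = compute_cell_stats(stack, nuclei, rings)
        idx = match_to_truth(stats, truth)
        cd8_expr = truth["CD8_level"].to_numpy()[idx]
        measured = stats["Opal520_ring_mean"].to_numpy()
        pos = cd8_expr > 0
        assert pos.any()
        np.testing.assert_allclose(measured[pos], cd8_expr[pos], atol=1e-6)
        np.testing.assert_allclose(measured[~pos], 0.0, atol=1e-6)

    def test_fully_clipped_ring_is_flagged_not_dropped(self):
        # nucleus fills the whole image: no room for any ring pixel
        labels = np.ones((16, 16), dtype=np.int32)
        nuclei = LabelImage(labels, PIXEL_SIZE)
        rings = expand_cytoplasm(nuclei, 2.0)
        stack = self._stack([np.ones((16, 16))])
        out = compute_cell_stats(stack, nuclei, rings)
        assert len(out) == 1
        assert bool(out.loc[0, "ring_missing"])
        assert np.isnan(out.loc[0, "c0_ring_mean"])
        assert np.isfinite(out.loc[0, "c0_nucleus_mean"])

    def test_areas_are_scale_equivariant(self):
        # same metric scene at two resolutions: um^2 areas agree within 5%
        # for the nucleus and the whole cell; the 2 um ring band alone is a
        # thin annulus whose discretized area is more pixel-size sensitive,
        # so it gets a 10% band
        areas = []
        for pixel_size, radius_px in ((PIXEL_SIZE, 8), (PIXEL_SIZE / 2, 16)):
            nuclei = _disk_labels((128, 128), [(64, 64)], radius_px, pixel_size)
            rings = expand_cytoplasm(nuclei, 2.0)
            nuc_area = nuclei.areas_um2()[0]
            ring_area = (rings.labels == 1).sum() * pixel_size**2
            areas.append((nuc_area, nuc_area + ring_area, ring_area))
        (n1, cell1, r1), (n2, cell2, r2) = areas
        assert abs(n1 - n2) / n1 < 0.05
        assert abs(cell1 - cell2) / cell1 < 0.05
        assert abs(r1 - r2) / r1 < 0.10
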