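"""Segmentation tests: thresholding, seeded separation of touching nuclei,
quality criteria with over-segmentation repair, border refinement, and
whole-movie segmentation against the simulator's ground-truth labels."""

import math

import numpy as np
import pytest
from scipy import ndimage

from nb4d.movie import Calibration
from nb4d.params import CellType, SegmentationConfig, default_imaging, type_i_preset
from nb4d.segment import (
    DegenerateHistogramError,
    apply_quality_criteria,
    auto_threshold,
    detect_nuclei,
    measure_objects,
    refine_borders,
    segment_movie,
    separate_touching,
    sphericity_of,
)
from nb4d.simulate import TruthCell, render_movie, simulate_lineage
from nb4d.validate import segmentation_iou

CAL = Calibration(voxel_xy=0.33, voxel_z=1.0, frame_interval=3.0)


def sphere_mask(shape, center_um, r_um, cal=CAL):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dz = ((zz + 0.5) * cal.voxel_z - center_um[2]) / r_um
    dy = ((yy + 0.5) * cal.voxel_xy - center_um[1]) / r_um
    dx = ((xx + 0.5) * cal.voxel_xy - center_um[0]) / r_um
    return dz**2 + dy**2 + dx**2 <= 1.0


class TestAutoThreshold:
    def test_two_valued_volume_exact_mask(self):
        vol = np.full((10, 20, 20), 10, dtype=np.uint8)
        fg = sphere_mask(vol.shape, (3.0, 3.0, 5.0), 2.0)
        vol[fg] = 200
        mask = auto_threshold(vol)
        assert np.array_equal(mask, fg)

    def test_constant_volume_raises(self):
        with pytest.raises(DegenerateHistogramError):
            auto_threshold(np.full((5, 5, 5), 42, dtype=np.uint8))

    def test_roi_restricts_histogram(self):
        vol = np.full((10, 10, 10), 10, dtype=np.uint8)
        vol[:5] = 200
        roi = np.zeros_like(vol, dtype=bool)
        roi[6:] = True
        with pytest.raises(DegenerateHistogramError):
            auto_threshold(vol, roi=roi)

    def test_noisy_frame_mask_covers_truth(self, noisy_render):
        movie, labels = noisy_render["movie"], noisy_render["labels"]
        t = 5
        mask = auto_threshold(movie.data[t])
        truth = labels.data[t] > 0
        assert (mask & truth).sum() / truth.sum() >= 0.90


class TestSeparateTouching:
    def test_single_sphere_identity(self):
        mask = sphere_mask((20, 40, 40), (5.0, 5.0, 10.0), 3.0)
        labels = separate_touching(mask, None, SegmentationConfig(), CAL)
        assert set(np.unique(labels)) == {0, 1}
        assert np.array_equal(labels > 0, mask)

    def test_touching_equal_spheres_split_at_midplane(self):
        # centers 8 µm apart in x, radii 5 µm -> overlap; split plane x = 10
        cfg = SegmentationConfig(max_nucleus_volume=2000.0)
        m1 = sphere_mask((24, 64, 64), (6.0, 8.0, 12.0), 5.0)
        m2 = sphere_mask((24, 64, 64), (14.0, 8.0, 12.0), 5.0)
        mask = m1 | m2
        labels = separate_touching(mask, None, cfg, CAL)
        ids = np.unique(labels)[1:]
        assert len(ids) == 2
        # every voxel more than 1 voxel from the midplane belongs to the
        # correct side
        xs = (np.arange(mask.shape[2]) + 0.5) * CAL.voxel_xy
        midplane = 10.0
        for lab in ids:
            zz, yy, xx = np.nonzero(labels == lab)
            side = np.sign(np.mean(xs[xx] - midplane))
            wrong = np.abs(xs[xx] - midplane) > CAL.voxel_xy
            assert np.all(np.sign(xs[xx][wrong] - midplane) == side)

    def test_dumbbell_unequal_spheres_counts(self):
        cfg = SegmentationConfig(max_nucleus_volume=2000.0)
        big = sphere_mask((24, 64, 64), (6.0, 8.0, 12.0), 4.0)
        small = sphere_mask((24, 64, 64), (11.5, 8.0, 12.0), 2.5)
        mask = big | small
        labels = separate_touching(mask, None, cfg, CAL)
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        assert len(ids) == 2
        counts = np.sort(counts)
        assert counts[1] == pytest.approx(big.sum(), rel=0.15)
        assert counts[0] == pytest.approx(small.sum(), rel=0.15)


class TestQualityCriteria:
    def test_speck_removed(self):
        labels = np.zeros((10, 20, 20), dtype=np.int32)
        labels[5, 10, 10:12] = 1
        intensity = np.full(labels.shape, 100, dtype=np.uint8)
        out, objs = apply_quality_criteria(labels, intensity, SegmentationConfig(), CAL)
        assert out.max() == 0 and objs == []

    def test_split_sphere_hemispheres_merged(self):
        mask = sphere_mask((20, 40, 40), (5.0, 5.0, 10.0), 2.5)
        labels = np.zeros(mask.shape, dtype=np.int32)
        xs_mid = int(round(5.0 / CAL.voxel_xy))
        labels[mask] = 1
        half = mask.copy()
        half[:, :, xs_mid:] = False
        labels[half] = 2
        sph_hemi = sphericity_of(labels == 2, CAL)
        sph_full = sphericity_of(mask, CAL)
        assert sph_full > sph_hemi  # merged shape is more spherical
        cfg = SegmentationConfig(min_sphericity=min(0.95, sph_hemi + 0.01))
        intensity = np.where(mask, 200, 10).astype(np.uint8)
        out, objs = apply_quality_criteria(labels, intensity, cfg, CAL)
        assert len(objs) == 1
        assert objs[0].voxel_count == mask.sum()

    def test_valid_nucleus_unchanged(self):
        mask = sphere_mask((20, 40, 40), (5.0, 5.0, 10.0), 2.5)
        labels = mask.astype(np.int32)
        intensity = np.where(mask, 200, 10).astype(np.uint8)
        out, objs = apply_quality_criteria(labels, intensity, SegmentationConfig(), CAL)
        assert np.array_equal(out, labels)
        assert len(objs) == 1

    def test_lowering_min_volume_never_decreases_object_count(self, noisy_render):
        frame = noisy_render["movie"].data[10]
        cal = noisy_render["movie"].calibration
        counts = []
        for mv in (30.0, 15.0, 5.0):
            cfg = SegmentationConfig(min_nucleus_volume=mv)
            _, objs = detect_nuclei(frame, cfg, cal, 10)
            counts.append(len(objs))
        assert counts == sorted(counts)


class TestRefineBorders:
    def test_exact_support_fixed_point(self):
        mask = sphere_mask((20, 40, 40), (5.0, 5.0, 10.0), 2.5)
        labels = mask.astype(np.int32)
        intensity = np.where(mask, 200.0, 10.0).astype(np.float32)
        out = refine_borders(labels, intensity, SegmentationConfig(), CAL)
        assert np.array_equal(out, labels)

    def test_dilated_label_recovers_support(self):
        mask = sphere_mask((20, 40, 40), (5.0, 5.0, 10.0), 2.5)
        dilated = ndimage.binary_dilation(mask, iterations=2)
        labels = dilated.astype(np.int32)
        intensity = np.where(mask, 200.0, 10.0).astype(np.float32)
        out = refine_borders(labels, intensity, SegmentationConfig(), CAL)
        inter = ((out > 0) & mask).sum()
        union = ((out > 0) | mask).sum()
        assert inter / union >= 0.9

    def test_adjacent_labels_stay_disjoint(self):
        m1 = sphere_mask((24, 64, 64), (6.0, 8.0, 12.0), 4.0)
        m2 = sphere_mask((24, 64, 64), (14.5, 8.0, 12.0), 4.0)
        labels = np.zeros(m1.shape, dtype=np.int32)
        labels[m1] = 1
        labels[m2 & ~m1] = 2
        intensity = np.where(m1 | m2, 200.0, 10.0).astype(np.float32)
        out = refine_borders(labels, intensity, SegmentationConfig(), CAL)
        assert ((out == 1) & (out == 2)).sum() == 0
        assert set(np.unique(out)) <= {0, 1, 2}


class TestDetectNuclei:
    def test_single_sphere_one_object_volume(self, clean_render):
        movie, labels = clean_render["movie"], clean_render["labels"]
        cal = movie.calibration
        t = 0
        lab, objs = detect_nuclei(movie.data[t], SegmentationConfig(), cal, t)
        truth = labels.data[t]
        nb_truth_vox = (truth == 1).sum()
        big = max(objs, key=lambda o: o.volume)
        assert big.voxel_count == pytest.approx(nb_truth_vox, rel=0.10)

    def test_two_distant_spheres_centroids(self):
        imaging = default_imaging(seed=2, psf_sigma_xy=0.0, psf_sigma_z=0.0)
        vol = 4.0 / 3.0 * math.pi * 27.0
        cells = []
        for i, pos in enumerate([(5.0, 5.0, 10.0), (16.0, 16.0, 30.0)]):
            c = TruthCell(cell_id=i + 1, parent_id=None, cell_type=CellType.NB,
                          birth_time=0.0, dispersal_min=0.0, mobile=False)
            c.volume_segments.append((0.0, 10.0, vol, vol))
            c.positions[-1] = np.array(pos)
            cells.append(c)
        movie, labels = render_movie(cells, imaging, 3.0, noise=False, blur=False)
        lab, objs = detect_nuclei(movie.data[0], SegmentationConfig(), movie.calibration, 0)
        assert len(objs) == 2
        got = sorted(o.centroid for o in objs)
        for (cx, cy, cz), pos in zip(got, [(5.0, 5.0, 10.0), (16.0, 16.0, 30.0)]):
            assert abs(cx - pos[0]) <= imaging.voxel_xy
            assert abs(cy - pos[1]) <= imaging.voxel_xy
            assert abs(cz - pos[2]) <= imaging.voxel_z

    def test_volume_calibration_identity(self, noisy_render):
        movie = noisy_render["movie"]
        cal = movie.calibration
        _, objs = detect_nuclei(movie.data[3], SegmentationConfig(), cal, 3)
        assert objs
        for o in objs:
            assert o.volume == pytest.approx(o.voxel_count * cal.voxel_volume)


class TestSegmentMovie:
    def test_oracle_iou_on_clean_render(self, clean_render, seg_config):
        movie, labels = clean_render["movie"], clean_render["labels"]
        per_frame, seg, nuclei = segment_movie(movie, seg_config)
        ious = []
        for t in range(movie.n_frames):
            ious.extend(segmentation_iou(seg, labels, t).values())
        assert min(ious) >= 0.9

    def test_object_counts_match_truth_on_clean_render(self, clean_render, seg_config):
        movie, labels = clean_render["movie"], clean_render["labels"]
        per_frame, seg, nuclei = segment_movie(movie, seg_config)
        match = 0
        for t in range(movie.n_frames):
            truth_n = len(np.unique(labels.data[t])) - 1
            if len(per_frame[t]) == truth_n:
                match += 1
        assert match / movie.n_frames >= 0.95

    def test_all_background_movie_empty_table(self):
        from nb4d.movie import Movie4D

        data = np.full((3, 10, 16, 16), 7, dtype=np.uint8)
        movie = Movie4D(data=data, calibration=CAL)
        per_frame, seg, nuclei = segment_movie(movie, SegmentationConfig())
        assert len(nuclei) == 0
        assert seg.data.max() == 0

    def test_dispersal_frames_lack_dividing_cell(self, noisy_render, seg_config):
        movie, labels = noisy_render["movie"], noisy_render["labels"]
        cells = noisy_render["cells"]
        interval = movie.calibration.frame_interval
        per_frame, seg, nuclei = segment_movie(movie, seg_config)
        root = cells[0]
        nebd = root.nebd_times[0]
        gap = [t for t in range(movie.n_frames)
               if nebd <= t * interval < nebd + root.dispersal_min]
        assert gap
        for t in gap:
            # no segmented object may sit on the dispersed cell's position
            pos = root.positions[t]
            for o in per_frame[t]:
                d = np.linalg.norm(np.asarray(o.centroid) - pos)
                assert d > 2.0

    def test_label_disjointness_by_construction(self, noisy_render, seg_config):
        movie = noisy_render["movie"]
        _, seg, nuclei = segment_movie(movie, seg_config)
        # voxel_count sums must equal the labelled voxel count (no overlap)
        for t in range(0, movie.n_frames, 7):
            total = (seg.data[t] > 0).sum()
            assert nuclei[nuclei.frame == t].voxel_count.sum() == total
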