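"""Ratio maps, NAWM reference, mirroring and the 2X threshold."""

import numpy as np
import pytest

from smritrack import (
    BinaryMask,
    NawmReference,
    make_timepoint,
    mirror_nawm,
    nawm_reference,
    ratio_map,
    segment_timepoint,
    threshold_mask,
)
from smritrack.errors import EmptyMaskError, GridMismatchError, ReferenceRegionError


class TestRatioMap:
    def test_simple_ratio(self, map_factory):
        r = ratio_map(map_factory(2.0, "CHO"), map_factory(1.0, "NAA"))
        assert np.allclose(r.values[r.coverage], 2.0)
        assert r.metabolite == "CHO_NAA_RATIO"

    def test_zero_naa_voxel_excluded(self, map_factory, geom):
        naa_vals = np.ones(geom.shape)
        naa_vals[0, 0, 0] = 0.0
        r = ratio_map(map_factory(2.0, "CHO"), map_factory(naa_vals, "NAA"))
        assert not r.coverage[0, 0, 0]
        assert r.coverage.sum() == np.prod(geom.shape) - 1

    def test_coverage_intersection(self, map_factory, geom):
        cov_cho = np.ones(geom.shape, bool)
        cov_cho[:3] = False
        cov_naa = np.ones(geom.shape, bool)
        cov_naa[7:] = False
        r = ratio_map(
            map_factory(2.0, "CHO", coverage=cov_cho),
            map_factory(1.0, "NAA", coverage=cov_naa),
        )
        assert np.array_equal(r.coverage, cov_cho & cov_naa)

    def test_geometry_mismatch_fails(self, map_factory):
        from smritrack import GridGeometry

        other = GridGeometry((5, 5, 5), (1.0, 1.0, 1.0))
        with pytest.raises(GridMismatchError):
            ratio_map(map_factory(1.0, "CHO"),
                      map_factory(1.0, "NAA", geometry=other))


class TestNawmReference:
    def test_constant_ratio(self, map_factory, mask_factory):
        nawm = mask_factory([(i, j, 0) for i in range(10) for j in range(10)],
                            label="NAWM")
        ref = nawm_reference(map_factory(1.0, "CHO_NAA_RATIO"), nawm)
        assert ref.mean_ratio == pytest.approx(1.0)
        assert ref.n_voxels == 100

    def test_arithmetic_mean(self, map_factory, mask_factory, geom):
        vals = np.ones(geom.shape)
        voxels = [(0, 0, 0), (0, 0, 1), (0, 0, 2)]
        for v, x in zip(voxels, (0.8, 1.0, 1.2)):
            vals[v] = x
        # pad the region to satisfy the 50-voxel minimum at the same mean
        extra = [(i, 5, 5) for i in range(10)] + [(i, 6, 6) for i in range(10)]
        for i, v in enumerate(extra):
            vals[v] = 0.8 if i % 2 == 0 else 1.2
        nawm = mask_factory(voxels + extra, label="NAWM")
        ref = nawm_reference(map_factory(vals, "CHO_NAA_RATIO"), nawm,
                             min_voxels=20)
        assert ref.mean_ratio == pytest.approx(1.0)

    def test_too_small_region_fails_naming_shortfall(self, map_factory,
                                                     mask_factory):
        nawm = mask_factory([(0, 0, 0)], label="NAWM")
        with pytest.raises(ReferenceRegionError, match="1 voxels"):
            nawm_reference(map_factory(1.0, "CHO_NAA_RATIO"), nawm)

    def test_empty_intersection_fails(self, map_factory, mask_factory, geom):
        cov = np.zeros(geom.shape, bool)
        cov[9, 9, 9] = True
        nawm = mask_factory([(0, 0, 0)], label="NAWM")
        with pytest.raises(ReferenceRegionError):
            nawm_reference(map_factory(1.0, "CHO_NAA_RATIO", coverage=cov), nawm)


class TestMirrorNawm:
    def test_left_lesion_mirrors_right(self, mask_factory, geom):
        brain = BinaryMask("BRAIN", np.ones(geom.shape, bool), geom)
        lesion = mask_factory([(1, 4, 4), (2, 4, 4)], label="FLAIR")
        mirrored = mirror_nawm(lesion, brain)
        assert mirrored.n_voxels == lesion.n_voxels
        assert mirrored.values[8, 4, 4] and mirrored.values[7, 4, 4]
        assert not mirrored.values[:5].any()

    def test_midline_overlap_removed(self, mask_factory, geom):
        brain = BinaryMask("BRAIN", np.ones(geom.shape, bool), geom)
        # straddles the mid-plane: its mirror overlaps itself
        lesion = mask_factory([(4, 4, 4), (5, 4, 4), (6, 4, 4)], label="FLAIR")
        mirrored = mirror_nawm(lesion, brain)
        assert not (mirrored.values & lesion.values).any()

    def test_empty_lesion_fails(self, mask_factory, geom):
        brain = BinaryMask("BRAIN", np.ones(geom.shape, bool), geom)
        with pytest.raises(EmptyMaskError):
            mirror_nawm(mask_factory([], label="FLAIR"), brain)


class TestThresholdMask:
    def test_threshold_is_inclusive(self, map_factory, geom):
        vals = np.ones(geom.shape)
        vals[3, 3, 3] = 2.0  # exactly at 2 x reference
        vals[4, 4, 4] = 1.999999
        ref = NawmReference(1.0, 100, "MANUAL_MASK")
        mask = threshold_mask(map_factory(vals, "CHO_NAA_RATIO"), ref,
                              min_component_cc=0.0)
        assert mask.values[3, 3, 3]
        assert not mask.values[4, 4, 4]

    def test_all_below_threshold_empty(self, map_factory):
        ref = NawmReference(1.0, 100, "MANUAL_MASK")
        mask = threshold_mask(map_factory(1.5, "CHO_NAA_RATIO"), ref,
                              min_component_cc=0.0)
        assert mask.is_empty()

    def test_small_component_filter(self, map_factory, geom):
        vals = np.ones(geom.shape)
        vals[0:3, 0:3, 0:3] = 3.0  # 27-voxel blob = 0.027 cc at 1 mm
        vals[9, 9, 9] = 3.0  # single stray voxel
        ref = NawmReference(1.0, 100, "MANUAL_MASK")
        mask = threshold_mask(map_factory(vals, "CHO_NAA_RATIO"), ref,
                              min_component_cc=0.01)
        assert mask.values[1, 1, 1]
        assert not mask.values[9, 9, 9]

    def test_monotone_in_factor(self, map_factory, geom):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 4.0, geom.shape)
        ref = NawmReference(1.0, 100, "MANUAL_MASK")
        rmap = map_factory(vals, "CHO_NAA_RATIO")
        prev = None
        for factor in (3.0, 2.5, 2.0, 1.5):
            mask = threshold_mask(rmap, ref, factor=factor, min_component_cc=0.0)
            if prev is not None:
                assert not (prev.values & ~mask.values).any()  # superset
            prev = mask

    def test_scale_invariance_of_biomarker(self, noiseless_config):
        """Scaling Cho and NAA by one constant leaves the segmentation fixed."""
        tp = make_timepoint(noiseless_config, -1.0)
        mask1, _ = segment_timepoint(tp.cho, tp.naa, nawm=tp.masks["NAWM"])
        from smritrack import MetaboliteMap

        scale = 7.3
        cho2 = MetaboliteMap("CHO", tp.cho.values * scale, tp.cho.coverage,
                             tp.cho.geometry)
        naa2 = MetaboliteMap("NAA", tp.naa.values * scale, tp.naa.coverage,
                             tp.naa.geometry)
        mask2, _ = segment_timepoint(cho2, naa2, nawm=tp.masks["NAWM"])
        assert np.array_equal(mask1.values, mask2.values)

    def test_never_outside_coverage(self, map_factory, geom):
        cov = np.zeros(geom.shape, bool)
        cov[:5] = True
        ref = NawmReference(1.0, 100, "MANUAL_MASK")
        mask = threshold_mask(map_factory(5.0, "CHO_NAA_RATIO", coverage=cov),
                              ref, min_component_cc=0.0)
        assert not (mask.values & ~cov).any()

    def test_noiseless_phantom_recovers_planted_mask(self, noiseless_config):
        tp = make_timepoint(noiseless_config, -1.0)
        mask, ref = segment_timepoint(tp.cho, tp.naa, nawm=tp.masks["NAWM"],
                                      min_component_cc=0.0)
        assert ref.mean_ratio == pytest.approx(
            noiseless_config.nawm_cho / noiseless_config.nawm_naa, rel=1e-9
        )
        assert np.array_equal(mask.values, tp.masks["GROUND_TRUTH"].values)
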