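"""Vessel reference measurement and the three-compartment partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdctperf import (
    VesselReference,
    compartment_thresholds,
    compartment_volumes,
    measure_vessel_reference,
    segment_compartments,
)
from sdctperf.segmentation import OUTSIDE, PERFDEF, PERFNORM, VES

from conftest import make_volume

REF = VesselReference(id_mpa=14.1, id_la=8.9, n_mpa=10, n_la=10)


def oracle_labels(idi, lung, t_low, t_high):
    """Independent per-voxel if/else reference implementation."""
    out = np.zeros(idi.shape, dtype=np.uint8)
    for i in np.ndindex(idi.shape):
        if not lung[i]:
            out[i] = OUTSIDE
        elif idi[i] <= t_low:
            out[i] = PERFDEF
        elif idi[i] <= t_high:
            out[i] = PERFNORM
        else:
            out[i] = VES
    return out


class TestVesselReference:
    def test_mean_of_constant_roi(self):
        idi = np.full((6, 6, 6), 1.0)
        idi[:3] = 14.0
        idi[3:] = 8.0
        mpa = np.zeros_like(idi); mpa[:3] = 1
        la = np.zeros_like(idi); la[3:] = 1
        ref = measure_vessel_reference(
            make_volume(idi), make_volume(mpa, "mask"), make_volume(la, "mask"))
        assert ref.id_mpa == pytest.approx(14.0)
        assert ref.id_la == pytest.approx(8.0)

    def test_two_voxel_mean(self):
        idi = np.zeros((2, 1, 1)); idi[0] = 8.0; idi[1] = 10.0
        mpa = np.ones_like(idi)
        la = np.ones_like(idi)
        ref = measure_vessel_reference(
            make_volume(idi), make_volume(mpa, "mask"), make_volume(la, "mask"))
        assert ref.id_mpa == pytest.approx(9.0)

    def test_empty_roi_raises(self):
        idi = make_volume(np.ones((3, 3, 3)))
        full = make_volume(np.ones((3, 3, 3)), "mask")
        empty = make_volume(np.zeros((3, 3, 3)), "mask")
        with pytest.raises(ValueError, match="empty ROI"):
            measure_vessel_reference(idi, full, empty)

    def test_nonpositive_mean_raises(self):
        idi = make_volume(np.full((3, 3, 3), -1.0))
        full = make_volume(np.ones((3, 3, 3)), "mask")
        with pytest.raises(ValueError, match="non-positive"):
            measure_vessel_reference(idi, full, full)

    def test_low_contrast_warns(self, caplog):
        idi = make_volume(np.full((3, 3, 3), 3.0))
        full = make_volume(np.ones((3, 3, 3)), "mask")
        with caplog.at_level("WARNING"):
            measure_vessel_reference(idi, full, full)
        assert "below 5" in caplog.text


class TestThresholds:
    def test_published_reference_medians(self):
        t_low, t_high = compartment_thresholds(REF)
        assert t_low == pytest.approx(0.705)
        assert t_high == pytest.approx(4.45)

    def test_mpa_upper_variant(self):
        _, t_high = compartment_thresholds(REF, upper_reference="mpa")
        assert t_high == pytest.approx(7.05)

    def test_degenerate_thresholds_rejected(self):
        ref = VesselReference(id_mpa=100.0, id_la=9.0, n_mpa=5, n_la=5)
        with pytest.raises(ValueError, match="degenerate"):
            compartment_thresholds(ref)


class TestSegmentation:
    def test_representative_voxels(self):
        idi = np.array([[[0.5, 2.0, 6.0]]])
        lung = np.ones_like(idi)
        cmap = segment_compartments(make_volume(idi), make_volume(lung, "mask"), REF)
        assert cmap.labels[0, 0].tolist() == [PERFDEF, PERFNORM, VES]

    def test_boundary_voxel_at_t_low_is_perfdef(self):
        t_low = 0.05 * REF.id_mpa
        idi = np.full((1, 1, 1), t_low)
        cmap = segment_compartments(make_volume(idi),
                                    make_volume(np.ones_like(idi), "mask"), REF)
        assert cmap.labels[0, 0, 0] == PERFDEF

    def test_negative_voxels_counted(self):
        idi = np.array([[[-0.2, -0.1, 1.0]]])
        cmap = segment_compartments(make_volume(idi),
                                    make_volume(np.ones_like(idi), "mask"), REF)
        assert cmap.n_negative_clamped == 2
        assert cmap.labels[0, 0, 0] == PERFDEF

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_voxel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(12, 20, 3))
        idi = rng.normal(2.0, 3.0, shape)
        lung = rng.random(shape) > 0.3
        cmap = segment_compartments(make_volume(idi),
                                    make_volume(lung.astype(np.uint8), "mask"), REF)
        expected = oracle_labels(idi, lung, cmap.t_low, cmap.t_high)
        np.testing.assert_array_equal(cmap.labels, expected)

    def test_labels_zero_exactly_outside_lung(self, rng):
        idi = rng.normal(2, 3, (10, 10, 10))
        lung = rng.random((10, 10, 10)) > 0.5
        cmap = segment_compartments(make_volume(idi),
                                    make_volume(lung.astype(np.uint8), "mask"), REF)
        np.testing.assert_array_equal(cmap.labels > 0, lung)

    @given(c=st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(99)
        idi = rng.normal(2.0, 3.0, (8, 8, 8))
        lung = rng.random((8, 8, 8)) > 0.3
        lung_vol = make_volume(lung.astype(np.uint8), "mask")
        base = segment_compartments(make_volume(idi), lung_vol, REF)
        ref_c = VesselReference(REF.id_mpa * c, REF.id_la * c, REF.n_mpa, REF.n_la)
        scaled = segment_compartments(make_volume(idi * c), lung_vol, ref_c)
        np.testing.assert_array_equal(base.labels, scaled.labels)

    def test_raising_mpa_only_moves_perfnorm_to_perfdef(self, rng):
        idi = rng.normal(2.0, 3.0, (12, 12, 12))
        lung_vol = make_volume((rng.random((12, 12, 12)) > 0.3).astype(np.uint8), "mask")
        lo = segment_compartments(make_volume(idi), lung_vol, REF)
        hi_ref = VesselReference(REF.id_mpa * 1.5, REF.id_la, REF.n_mpa, REF.n_la)
        hi = segment_compartments(make_volume(idi), lung_vol, hi_ref)
        changed = lo.labels != hi.labels
        assert np.all(lo.labels[changed] == PERFNORM)
        assert np.all(hi.labels[changed] == PERFDEF)


class TestCompartmentVolumes:
    def test_known_counts(self):
        labels = np.zeros((10, 10, 10), np.uint8)
        flat = labels.ravel()
        flat[:390] = PERFDEF
        flat[390:1000] = PERFNORM
        from sdctperf.segmentation import CompartmentMap
        cmap = CompartmentMap(labels, 0.705, 4.45, 0)
        vols = compartment_volumes(cmap, (1.0, 1.0, 1.0))
        assert vols.v_perfdef_pct == pytest.approx(39.0)
        assert vols.total_lung_ml == pytest.approx(1.0)

    def test_all_perfnorm(self):
        labels = np.full((5, 5, 5), PERFNORM, np.uint8)
        from sdctperf.segmentation import CompartmentMap
        vols = compartment_volumes(CompartmentMap(labels, 0.7, 4.4, 0), (1, 1, 1))
        assert (vols.v_perfdef_pct, vols.v_perfnorm_pct, vols.v_ves_pct) == (0, 100, 0)

    def test_partition_sums_to_100_on_random_maps(self, rng):
        from sdctperf.segmentation import CompartmentMap
        for _ in range(10):
            labels = rng.integers(0, 4, (9, 9, 9)).astype(np.uint8)
            if not (labels > 0).any():
                continue
            vols = compartment_volumes(CompartmentMap(labels, 0.7, 4.4, 0), (1, 1, 1))
            total = vols.v_perfdef_pct + vols.v_perfnorm_pct + vols.v_ves_pct
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_empty_lung_raises(self):
        from sdctperf.segmentation import CompartmentMap
        with pytest.raises(ValueError, match="no lung"):
            compartment_volumes(CompartmentMap(np.zeros((3, 3, 3), np.uint8), 0.7, 4.4, 0),
                                (1, 1, 1))
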