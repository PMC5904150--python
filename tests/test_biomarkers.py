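"""Biomarker vectors, the 1-based index convention, first-order stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dkitex import (
    VoiMask,
    apply_mr8,
    biomarker_descriptor,
    build_mr8_bank,
    descriptor_to_index,
    extract_biomarkers,
    first_order_statistics,
)
from dkitex.biomarkers import N_BIOMARKERS, concatenate_modalities
from dkitex.mr8 import CHANNEL_NAMES, ResponseChannels

# The seven (index, descriptor) anchor pairs that pin the convention.
ANCHOR_PAIRS = [
    (7, "mean of Gaussian filter response"),
    (9, "SD of Gaussian filter response"),
    (11, "p5 of Gaussian filter response"),
    (14, "median of Laplacian of Gaussian filter response"),
    (42, "p95 of bar filter (scale [3,1]) response"),
    (47, "p5 of bar filter (scale [6,2]) response"),
    (52, "kurtosis of bar filter (scale [12,4]) response"),
]


class TestIndexConvention:
    @pytest.mark.parametrize("index,descriptor", ANCHOR_PAIRS)
    def test_anchor_pairs(self, index, descriptor):
        assert biomarker_descriptor(index) == descriptor

    @given(index=st.integers(1, N_BIOMARKERS))
    @settings(max_examples=54, deadline=None)
    def test_descriptor_round_trip(self, index):
        assert descriptor_to_index(biomarker_descriptor(index)) == index

    def test_out_of_range_rejected(self):
        for bad in (0, 55, -3):
            with pytest.raises(IndexError):
                biomarker_descriptor(bad)


def _channels_from(arrays):
    return ResponseChannels(channels=dict(zip(CHANNEL_NAMES, arrays)))


class TestExtraction:
    def test_output_length_54(self):
        rng = np.random.default_rng(0)
        ch = _channels_from([rng.normal(size=(6, 6, 2)) for _ in range(9)])
        mask = np.ones((6, 6, 2), dtype=bool)
        vec = extract_biomarkers(ch, mask)
        assert vec.values.shape == (54,)
        assert np.all(np.isfinite(vec.values))

    def test_constant_voi_degenerate_stats(self):
        arrays = [np.full((5, 5, 2), 4.2) for _ in range(9)]
        vec = extract_biomarkers(_channels_from(arrays), np.ones((5, 5, 2), dtype=bool))
        # intensity channel occupies indices 1..6: mean, median, SD, kurt, p5, p95
        for idx in (1, 2, 5, 6):
            assert vec[idx] == pytest.approx(4.2, rel=1e-12)
        assert vec[3] <= 1e-12  # SD of a constant (float accumulation)

    def test_percentiles_match_order_statistic_oracle(self):
        values = np.arange(1.0, 101.0)
        rng = np.random.default_rng(3)
        shuffled = values.copy()
        rng.shuffle(shuffled)
        arrays = [shuffled.reshape(10, 10, 1)] * 9
        vec = extract_biomarkers(_channels_from(arrays), np.ones((10, 10, 1), dtype=bool))

        def oracle(q):  # linear interpolation of order statistics
            pos = q / 100 * 99
            lo, frac = int(np.floor(pos)), pos % 1
            v = np.sort(values)
            return v[lo] * (1 - frac) + v[min(lo + 1, 99)] * frac

        assert vec[5] == pytest.approx(oracle(5), rel=1e-12)
        assert vec[6] == pytest.approx(oracle(95), rel=1e-12)

    def test_mask_permutation_invariance(self):
        """Statistics depend only on the multiset of in-mask values."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=(6, 6, 1))
        arrays_a = [base] * 9
        perm = base.ravel()
        rng.shuffle(perm)
        arrays_b = [perm.reshape(6, 6, 1)] * 9
        mask = np.ones((6, 6, 1), dtype=bool)
        va = extract_biomarkers(_channels_from(arrays_a), mask)
        vb = extract_biomarkers(_channels_from(arrays_b), mask)
        assert np.allclose(va.values, vb.values)

    def test_small_voi_rejected(self):
        arrays = [np.ones((4, 4, 1))] * 9
        mask = np.zeros((4, 4, 1), dtype=bool)
        mask[0, :2, 0] = True  # 2 voxels < minimum of 10
        with pytest.raises(ValueError):
            extract_biomarkers(_channels_from(arrays), mask)

    def test_modality_concatenation_is_108_dki_first(self):
        rng = np.random.default_rng(1)
        ch = _channels_from([rng.normal(size=(6, 6, 1)) for _ in range(9)])
        mask = np.ones((6, 6, 1), dtype=bool)
        dki = extract_biomarkers(ch, mask, modality="DKI")
        flair = extract_biomarkers(ch, mask, modality="FLAIR")
        both = concatenate_modalities(dki, flair)
        assert both.shape == (108,)
        assert np.array_equal(both[:54], dki.values)


class TestFirstOrderStats:
    def test_small_closed_form_case(self):
        vol = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2).reshape(5, 2, 1)
        fo = first_order_statistics(vol, np.ones((5, 2, 1), dtype=bool))
        assert fo.mean == 3.0 and fo.median == 3.0
        # sample SD of duplicated {1..5}: sqrt(sum((x-3)^2)/(n-1)) over 10 values
        assert fo.sd == pytest.approx(np.sqrt(20.0 / 9.0), rel=1e-12)

    def test_symmetric_distribution_zero_skewness(self, rng):
        v = rng.normal(size=(100, 100, 10))
        fo = first_order_statistics(v, np.ones(v.shape, dtype=bool))
        assert abs(fo.skewness) < 0.05

    def test_standard_normal_excess_kurtosis_near_zero(self, rng):
        v = rng.standard_normal((100, 100, 10))
        fo = first_order_statistics(v, np.ones(v.shape, dtype=bool))
        assert abs(fo.kurtosis) <= 0.05

    def test_percentile_ordering_invariant(self, rng):
        v = rng.normal(5.0, 2.0, size=(10, 10, 3))
        fo = first_order_statistics(v, np.ones(v.shape, dtype=bool))
        assert fo.p5 <= fo.median <= fo.p95
        assert fo.sd >= 0

    def test_nan_voxels_excluded(self):
        v = np.ones((4, 4, 2)) * 3.0
        v[0, 0, 0] = np.nan
        fo = first_order_statistics(v, np.ones(v.shape, dtype=bool))
        assert fo.mean == 3.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            VoiMask(np.zeros((4, 4, 2), dtype=bool))
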