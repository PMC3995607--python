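"""Percentile estimator and the ROI biomarker panel."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulmopet import BinaryMask, ImageVolume, Modality, ModalityError
from pulmopet.uptake_biomarkers import UptakeSummary, percentile, summarize_roi


def percentile_oracle(values, p):
    """Brute-force empirical-CDF percentile: explicit rank interpolation."""
    s = sorted(float(v) for v in values)
    n = len(s)
    rank = (p / 100.0) * (n - 1)
    lo, hi = math.floor(rank), math.ceil(rank)
    frac = rank - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def test_rank_interpolation_example():
    assert percentile(np.arange(1, 101), 95) == pytest.approx(95.05)


@pytest.mark.parametrize("p", [0, 7, 33, 50, 80, 95, 100])
def test_constant_collection_and_boundaries(p):
    assert percentile([3.2] * 17, p) == 3.2
    vals = [5.0, 1.0, 9.0, 2.0]
    assert percentile(vals, 0) == 1.0
    assert percentile(vals, 100) == 9.0


def test_empty_or_nonfinite_rejected():
    with pytest.raises(ValueError, match="empty"):
        percentile([], 50)
    with pytest.raises(ValueError, match="non-finite"):
        percentile([1.0, np.nan], 50)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=200),
       st.floats(0, 100))
def test_matches_bruteforce_cdf_oracle(values, p):
    assert percentile(values, p) == pytest.approx(percentile_oracle(values, p),
                                                  rel=1e-9, abs=1e-9)


def _roi_volume(values):
    arr = np.zeros((3, 3, 3))
    mask = np.zeros((3, 3, 3), bool)
    flat = np.asarray(values, float)
    arr.ravel()[:flat.size] = flat
    mask.ravel()[:flat.size] = True
    vol = ImageVolume(arr, (1, 1, 1), Modality.PET_SUV)
    return vol, BinaryMask(mask)


def test_panel_over_exact_roi_voxels():
    vol, roi = _roi_volume([1.0, 2.0, 3.0, 4.0])
    s = summarize_roi(vol, roi)
    assert s.n_voxels == 4
    assert s.mean == 2.5
    assert s.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
    assert s.max == 4.0
    assert s.p80 <= s.p90 <= s.p95 <= s.max


def test_single_voxel_roi_sd_pinned_to_zero_with_warning():
    vol, roi = _roi_volume([2.0])
    with pytest.warns(UserWarning, match="single-voxel"):
        s = summarize_roi(vol, roi)
    assert (s.mean, s.sd, s.max, s.p80, s.p90, s.p95) == (2, 0, 2, 2, 2, 2)


def test_translation_equivariance_and_scale():
    vals = np.random.default_rng(1).lognormal(0, 0.3, 20)
    arr = np.zeros((3, 3, 3))
    arr.ravel()[:20] = vals
    mask = np.zeros((3, 3, 3), bool)
    mask.ravel()[:20] = True
    roi = BinaryMask(mask)
    a, b = 2.5, 1.0
    s0 = summarize_roi(ImageVolume(arr, (1, 1, 1), Modality.PET_SUV), roi)
    s1 = summarize_roi(ImageVolume(a * arr + b, (1, 1, 1), Modality.PET_SUV), roi)
    for stat in ("mean", "max", "p80", "p90", "p95"):
        assert getattr(s1, stat) == pytest.approx(a * getattr(s0, stat) + b)
    assert s1.sd == pytest.approx(a * s0.sd)


def test_dose_volume_rejected_and_invariants_enforced():
    arr = np.ones((3, 3, 3))
    roi = BinaryMask(np.ones((3, 3, 3), bool))
    with pytest.raises(ModalityError):
        summarize_roi(ImageVolume(arr, (1, 1, 1), Modality.DOSE), roi)
    with pytest.raises(ValueError, match="ordered"):
        UptakeSummary("SUV", 1, 0.1, max=1.0, p80=1.2, p90=1.1, p95=1.0, n_voxels=5)
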