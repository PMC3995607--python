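"""Lung segmentation against phantom ground truth."""
import numpy as np
import pytest

from pulmopet import (BinaryMask, ExclusionROI, ImageVolume, Modality,
                      SegmentationError, dice, extract_central_airway,
                      finalize_lung_roi, segment_lung_parenchyma, summarize_roi)
from pulmopet import synthetic_data as synth


def test_parenchyma_dice_against_truth(clean_phantom):
    truth = clean_phantom.truth.lung_mask.data | clean_phantom.truth.airway_mask.data
    mask = segment_lung_parenchyma(clean_phantom.ct)
    assert dice(mask.data, truth) >= 0.95
    assert mask.provenance  # every step recorded


def test_uniform_soft_tissue_is_an_error_not_an_empty_mask():
    ct = ImageVolume(np.full((48, 48, 48), 40.0), (2.5, 2.5, 2.5), Modality.CT_HU)
    with pytest.raises(SegmentationError):
        segment_lung_parenchyma(ct)


def test_cardiac_blob_lives_in_pet_not_ct():
    """Adding the cardiac hot spot leaves the CT-derived mask essentially unchanged."""
    base = synth.PhantomSpec(grid_shape=(96, 96, 96), seed=13,
                             include_tumor=False, include_diaphragm_coldspot=False,
                             include_cardiac_spillover=False)
    with_heart = synth.PhantomSpec(grid_shape=(96, 96, 96), seed=13,
                                   include_tumor=False, include_diaphragm_coldspot=False,
                                   include_cardiac_spillover=True)
    m0 = segment_lung_parenchyma(synth.generate_phantom(base).ct)
    m1 = segment_lung_parenchyma(synth.generate_phantom(with_heart).ct)
    assert dice(m0.data, m1.data) > 0.98


def test_airway_recovery_and_disjointness(default_phantom):
    par = segment_lung_parenchyma(default_phantom.ct)
    airway = extract_central_airway(default_phantom.ct, par)
    truth_airway = default_phantom.truth.airway_mask
    coverage = (airway.data & truth_airway.data).sum() / truth_airway.voxel_count
    assert coverage >= 0.90
    roi = finalize_lung_roi(par, airway)
    assert not (roi.data & airway.data).any()


def test_phantom_without_airway_yields_empty_mask_not_error():
    ph = synth.generate_phantom(synth.PhantomSpec(
        grid_shape=(96, 96, 96), seed=2, include_airway=False,
        include_cardiac_spillover=False, include_tumor=False,
        include_diaphragm_coldspot=False))
    par = segment_lung_parenchyma(ph.ct)
    airway = extract_central_airway(ph.ct, par)
    assert airway.voxel_count == 0


def test_finalize_identity_and_voxel_count_monotone(default_phantom):
    par = segment_lung_parenchyma(default_phantom.ct)
    empty = BinaryMask(np.zeros(par.shape, bool))
    roi = finalize_lung_roi(par, empty, [])
    assert roi.voxel_count == par.voxel_count
    airway = extract_central_airway(default_phantom.ct, par)
    excl = [ExclusionROI(m, lab) for lab, m in default_phantom.truth.exclusions.items()]
    roi_full = finalize_lung_roi(par, airway, excl)
    assert roi_full.voxel_count <= par.voxel_count
    assert not (roi_full.data & ~par.data).any()   # subset of the parenchyma


def test_exclusions_shrink_suv95_error_monotonically(default_phantom):
    """Each artifact exclusion supplied moves measured SUV95 toward the truth."""
    truth_p95 = default_phantom.truth.suv_summary.p95
    par = segment_lung_parenchyma(default_phantom.ct)
    airway = extract_central_airway(default_phantom.ct, par)
    excl_all = [ExclusionROI(m, lab) for lab, m in default_phantom.truth.exclusions.items()]

    def err(exclusions):
        roi = finalize_lung_roi(par, airway, exclusions)
        return abs(summarize_roi(default_phantom.pet, roi).p95 - truth_p95)

    assert err(excl_all) <= 0.03
    assert err([]) > err(excl_all)


def test_exclusions_covering_everything_is_an_error(default_phantom):
    par = segment_lung_parenchyma(default_phantom.ct)
    everything = ExclusionROI(BinaryMask(np.ones(par.shape, bool)), "spill_over")
    with pytest.raises(SegmentationError, match="empty"):
        finalize_lung_roi(par, BinaryMask(np.zeros(par.shape, bool)), [everything])


def test_exclusion_label_vocabulary_is_fixed():
    with pytest.raises(ValueError, match="label"):
        ExclusionROI(BinaryMask(np.zeros((48, 48, 48), bool)), "liver")
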