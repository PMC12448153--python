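"""Segmentation metrics and lesion-detection evaluation.

DSC is cross-checked against SimpleITK's overlap filter (an independent
codebase) and ASSD against a brute-force pairwise-distance oracle over
the same boundary definition.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ncrfseg.metrics import (PatientMasks, assd, boundary_voxels,
                             detection_eval, dsc, metrics_report,
                             per_part_dsc, ravd, split_parts)

SPACING = (3.0, 0.625, 0.625)


def _masks(pred, ref, spacing=SPACING):
    return PatientMasks(np.asarray(pred), np.asarray(ref), spacing)


# -- DSC ---------------------------------------------------------------

def test_dsc_identical_disjoint_and_empty():
    a = np.zeros((2, 4, 4), int)
    a[0, :2] = 1
    b = np.zeros((2, 4, 4), int)
    b[1, 2:] = 1
    assert dsc(_masks(a, a), 1) == 1.0
    assert dsc(_masks(a, b), 1) == 0.0
    assert dsc(_masks(np.zeros((2, 2, 2), int),
                      np.zeros((2, 2, 2), int)), 1) == 1.0


def test_dsc_half_overlap_cubes():
    """|P| = |G| = 8 with 4 shared voxels gives 2*4/16 = 0.5."""
    pred = np.zeros((4, 4, 4), int)
    ref = np.zeros((4, 4, 4), int)
    pred[0:2, 0:2, 0:2] = 1        # 8 voxels
    ref[0:2, 0:2, 1:3] = 1         # 8 voxels, 4 shared
    assert dsc(_masks(pred, ref), 1) == 0.5


def test_dsc_symmetric(rng):
    a = rng.integers(0, 2, (3, 5, 5))
    b = rng.integers(0, 2, (3, 5, 5))
    assert dsc(_masks(a, b), 1) == dsc(_masks(b, a), 1)


# -- RAVD --------------------------------------------------------------

def test_ravd_examples():
    ref = np.zeros((2, 4, 4), int)
    ref[0, :2, :2] = 1             # 4 voxels
    pred = np.zeros((2, 4, 4), int)
    pred[:, :2, :2] = 1            # 8 voxels: doubled volume
    assert ravd(_masks(ref, ref), 1) == 0.0
    assert ravd(_masks(pred, ref), 1) == 1.0
    with pytest.raises(ValueError):
        ravd(_masks(ref, np.zeros_like(ref)), 1)


def test_ravd_independent_of_spacing(rng):
    a = rng.integers(0, 2, (3, 6, 6))
    b = np.clip(a + rng.integers(0, 2, a.shape), 0, 1)
    r1 = ravd(_masks(a, b, (3.0, 0.625, 0.625)), 1)
    r2 = ravd(_masks(a, b, (1.0, 1.0, 1.0)), 1)
    assert r1 == r2


# -- ASSD --------------------------------------------------------------

def test_assd_identical_masks_is_zero():
    m = np.zeros((3, 5, 5), int)
    m[1, 1:4, 1:4] = 1
    assert assd(_masks(m, m), 1) == 0.0


def test_assd_offset_slabs_fixture():
    """Parallel unit-thickness slabs, 3 in-plane voxels apart at 0.625 mm
    spacing: every boundary voxel is 1.875 mm from the other surface."""
    pred = np.zeros((3, 8, 64), int)
    ref = np.zeros((3, 8, 64), int)
    pred[:, 3, :] = 1
    ref[:, 6, :] = 1
    spacing = (0.625, 0.625, 0.625)
    assert assd(_masks(pred, ref, spacing), 1) == pytest.approx(1.875)


def test_assd_symmetric(rng):
    a = np.zeros((3, 8, 8), int)
    b = np.zeros((3, 8, 8), int)
    a[1, 2:5, 2:5] = 1
    b[1, 3:7, 3:7] = 1
    assert assd(_masks(a, b), 1) == pytest.approx(assd(_masks(b, a), 1))


def test_assd_empty_surface_rejected():
    m = np.zeros((2, 4, 4), int)
    full = m.copy()
    full[0, 0, 0] = 1
    with pytest.raises(ValueError, match="surface"):
        assd(_masks(m, full), 1)


def test_assd_matches_bruteforce_pairwise_oracle(rng):
    """EDT-based distances equal explicit pairwise minima over boundary
    voxel sets, on random blobby masks."""
    from scipy import ndimage
    for seed in range(20):
        r = np.random.default_rng(seed)
        a = ndimage.binary_dilation(r.random((4, 9, 9)) > 0.93,
                                    iterations=2)
        b = ndimage.binary_dilation(r.random((4, 9, 9)) > 0.93,
                                    iterations=2)
        if not a.any() or not b.any():
            continue
        spacing = np.asarray(SPACING)
        sa = np.argwhere(boundary_voxels(a)) * spacing
        sb = np.argwhere(boundary_voxels(b)) * spacing
        d = cdist(sa, sb)
        expected = (d.min(1).sum() + d.min(0).sum()) / (len(sa) + len(sb))
        got = assd(_masks(a.astype(int), b.astype(int)), 1)
        assert got == pytest.approx(expected, rel=1e-9)


def test_dsc_matches_simpleitk(rng):
    sitk = pytest.importorskip("SimpleITK")
    for seed in range(20):
        r = np.random.default_rng(seed)
        a = (r.random((3, 8, 8)) > 0.6).astype(np.uint8)
        b = (r.random((3, 8, 8)) > 0.6).astype(np.uint8)
        f = sitk.LabelOverlapMeasuresImageFilter()
        f.Execute(sitk.GetImageFromArray(a), sitk.GetImageFromArray(b))
        assert dsc(_masks(a, b), 1) == pytest.approx(f.GetDiceCoefficient(),
                                                     abs=1e-6)


# -- apex / mid-gland / base -------------------------------------------

def test_split_parts_counts():
    ref = np.zeros((9, 4, 4), int)
    ref[1:8, 1, 1] = 1             # 7 foreground slices
    parts = split_parts(_masks(ref, ref))
    assert list(parts["apex"]) == [1, 2]
    assert list(parts["mid"]) == [3, 4, 5]
    assert list(parts["base"]) == [6, 7]
    concat = np.concatenate([parts["apex"], parts["mid"], parts["base"]])
    np.testing.assert_array_equal(concat, np.arange(1, 8))


def test_split_parts_requires_five_slices():
    ref = np.zeros((6, 4, 4), int)
    ref[1:5, 1, 1] = 1
    with pytest.raises(ValueError, match="apex"):
        split_parts(_masks(ref, ref))


def test_per_part_dsc_identical_masks():
    ref = np.zeros((8, 4, 4), int)
    ref[1:7, 1:3, 1:3] = 1
    scores = per_part_dsc(_masks(ref, ref), 1)
    assert scores == {"apex": 1.0, "mid": 1.0, "base": 1.0}


def test_metrics_report_identity():
    ref = np.zeros((6, 6, 6), int)
    ref[2:4, 2:4, 2:4] = 1
    ref[4, 2:4, 2:4] = 2
    report = metrics_report(_masks(ref, ref))
    for c in (1, 2):
        assert report[c]["dsc"] == 1.0
        assert report[c]["ravd"] == 0.0
        assert report[c]["assd"] == 0.0


# -- detection ---------------------------------------------------------

def _single_lesion(shape=(8, 32, 32), center=(4, 16, 16), radius_mm=3.0):
    grid = np.stack(np.meshgrid(*[np.arange(d) for d in shape],
                                indexing="ij"), -1)
    dist = np.sqrt((((grid - np.asarray(center)) * SPACING) ** 2).sum(-1))
    return (dist <= radius_mm).astype(np.uint8)


def test_peak_inside_lesion_is_perfect_at_zero_fp():
    lesions = _single_lesion()
    prob = np.zeros(lesions.shape)
    prob[4, 16, 16] = 0.9
    res = detection_eval(prob, lesions, SPACING)
    assert res.n_lesions == 1
    assert list(res.is_tp) == [True]
    assert res.sensitivity[0.5] == 1.0


def test_distant_peak_is_false_positive():
    lesions = _single_lesion()
    prob = np.zeros(lesions.shape)
    prob[4, 16, 32 - 2] = 0.9       # ~8.1 mm in-plane from lesion surface
    res = detection_eval(prob, lesions, SPACING)
    assert list(res.is_tp) == [False]
    assert res.sensitivity[3.0] == 0.0


def test_empty_probability_map_has_no_detections():
    lesions = _single_lesion()
    res = detection_eval(np.zeros(lesions.shape), lesions, SPACING)
    assert len(res.coordinates) == 0
    assert all(v == 0.0 for v in res.sensitivity.values())


def test_sensitivity_nondecreasing_in_fp_allowance(rng):
    lesions = _single_lesion()
    prob = rng.random(lesions.shape) * 0.5
    prob[4, 16, 16] = 0.95
    res = detection_eval(prob, lesions, SPACING)
    values = [res.sensitivity[op] for op in sorted(res.sensitivity)]
    assert values == sorted(values)
    assert res.is_tp.sum() + (~res.is_tp).sum() == len(res.coordinates)


def test_missing_spacing_rejected():
    with pytest.raises(ValueError, match="spacing"):
        detection_eval(np.zeros((2, 4, 4)), np.zeros((2, 4, 4)), None)
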