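"""3D per-patient segmentation metrics and lesion-detection analysis.

DSC and RAVD are voxel-count metrics; ASSD is a physical surface
distance, computed between boundary voxel sets (foreground voxels with at
least one face-adjacent background neighbour) via Euclidean distance
transforms weighted by the voxel spacing.  The apex / mid-gland / base
breakdown takes, among the slices containing any foreground, the first
two as apex and the last two as base.

Lesion detection follows the free-response convention: local maxima of a
probability map are detections, a detection is a true positive when it
lies within 5 mm of any reference lesion voxel, and sensitivity is
reported at fixed false-positives-per-patient allowances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)   # 6-connectivity
FULL_STRUCTURE = ndimage.generate_binary_structure(3, 3)   # 26-connectivity


@dataclass
class PatientMasks:
    predicted: np.ndarray
    reference: np.ndarray
    spacing: tuple = (3.0, 0.625, 0.625)

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted)
        self.reference = np.asarray(self.reference)
        if self.predicted.shape != self.reference.shape:
            raise ValueError("predicted and reference shapes differ")
        if min(self.spacing) <= 0:
            raise ValueError("voxel spacing must be positive")


def dsc(masks: PatientMasks, class_id: int) -> float:
    """Dice similarity 2|P n G| / (|P| + |G|); 1 when both are empty."""
    p = masks.predicted == class_id
    g = masks.reference == class_id
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def ravd(masks: PatientMasks, class_id: int) -> float:
    """Relative absolute volume difference |V_p - V_g| / V_g."""
    vp = int((masks.predicted == class_id).sum())
    vg = int((masks.reference == class_id).sum())
    if vg == 0:
        raise ValueError(f"reference volume for class {class_id} is empty")
    return abs(vp - vg) / vg


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 face-adjacent background neighbour."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=FACE_STRUCTURE,
                                    border_value=0)
    return mask & ~eroded


def assd(masks: PatientMasks, class_id: int) -> float:
    """Average symmetric surface distance in mm."""
    surf_p = boundary_voxels(masks.predicted == class_id)
    surf_g = boundary_voxels(masks.reference == class_id)
    if not surf_p.any() or not surf_g.any():
        raise ValueError(f"empty surface for class {class_id}")
    dt_g = ndimage.distance_transform_edt(~surf_g, sampling=masks.spacing)
    dt_p = ndimage.distance_transform_edt(~surf_p, sampling=masks.spacing)
    d_pg = dt_g[surf_p]
    d_gp = dt_p[surf_g]
    return float((d_pg.sum() + d_gp.sum()) / (d_pg.size + d_gp.size))


def split_parts(masks: PatientMasks) -> dict:
    """{apex, mid, base} slice-index arrays over foreground-bearing slices."""
    fg = np.flatnonzero((masks.reference > 0).any(axis=(1, 2)))
    if fg.size < 5:
        raise ValueError(
            "need at least 5 foreground-bearing slices for the "
            "apex (first two) / mid-gland / base (last two) convention")
    return {"apex": fg[:2], "mid": fg[2:-2], "base": fg[-2:]}


def per_part_dsc(masks: PatientMasks, class_id: int) -> dict:
    """DSC restricted to the apex / mid-gland / base slice subsets."""
    parts = split_parts(masks)
    return {name: dsc(PatientMasks(masks.predicted[idx], masks.reference[idx],
                                   masks.spacing), class_id)
            for name, idx in parts.items()}


def metrics_report(masks: PatientMasks, class_ids=None) -> dict:
    """Per-class DSC / RAVD / ASSD (NaN where a metric is undefined)."""
    if class_ids is None:
        class_ids = sorted(set(np.unique(masks.reference)) - {0})
    report = {}
    for c in class_ids:
        entry = {"dsc": dsc(masks, int(c))}
        try:
            entry["ravd"] = ravd(masks, int(c))
        except ValueError:
            entry["ravd"] = float("nan")
        try:
            entry["assd"] = assd(masks, int(c))
        except ValueError:
            entry["assd"] = float("nan")
        report[int(c)] = entry
    return report


# ---------------------------------------------------------------------
# lesion detection
# ---------------------------------------------------------------------

@dataclass
class DetectionResult:
    coordinates: np.ndarray          # (n, 3) retained detection voxels
    probabilities: np.ndarray        # (n,) peak values, descending
    is_tp: np.ndarray                # (n,) booleans
    lesion_ids: np.ndarray           # (n,) matched lesion label or -1
    n_lesions: int
    sensitivity: dict = field(default_factory=dict)   # {FP/patient: fraction}


def _local_maxima(prob: np.ndarray, min_peak: float) -> np.ndarray:
    """26-connected local maxima with peak probability >= min_peak."""
    footprint = np.ones((3, 3, 3), dtype=bool)
    peaks = (prob == ndimage.maximum_filter(prob, footprint=footprint)) \
        & (prob >= min_peak)
    coords = np.argwhere(peaks)
    # plateaus: keep one representative per connected plateau component
    if len(coords) > 1:
        labeled, n = ndimage.label(peaks, structure=FULL_STRUCTURE)
        coords = np.asarray(ndimage.center_of_mass(peaks, labeled,
                                                   range(1, n + 1)))
        coords = np.round(coords).astype(int)
    return coords


def detection_eval(probability_map: np.ndarray, reference_lesions: np.ndarray,
                   spacing: tuple,
                   fp_operating_points=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
                   min_peak: float = 0.1,
                   min_separation_mm: float = 5.0,
                   match_mm: float = 5.0) -> DetectionResult:
    """FROC-style evaluation of a probability map against lesion masks."""
    prob = np.asarray(probability_map, dtype=float)
    lesions = np.asarray(reference_lesions).astype(bool)
    if spacing is None:
        raise ValueError("voxel spacing is required: distances are physical")
    spacing = np.asarray(spacing, dtype=float)
    if prob.shape != lesions.shape:
        raise ValueError("probability map and lesion mask shapes differ")

    lesion_labels, n_lesions = ndimage.label(lesions, structure=FULL_STRUCTURE)
    coords = _local_maxima(prob, min_peak)
    order = np.argsort(-prob[tuple(coords.T)]) if len(coords) else []
    coords = coords[order] if len(coords) else coords.reshape(0, 3)

    # greedy physical non-maximum suppression, strongest peak first
    kept = []
    for c in coords:
        if all(np.linalg.norm((c - k) * spacing) >= min_separation_mm
               for k in kept):
            kept.append(c)
    coords = np.asarray(kept, dtype=int).reshape(-1, 3)

    if n_lesions:
        # nearest-lesion distance and the index map pointing at it
        dt, indices = ndimage.distance_transform_edt(
            ~lesions, sampling=spacing, return_indices=True)
    # classify; duplicate hits on an already-detected lesion are dropped
    retained, is_tp, ids = [], [], []
    seen = set()
    for c in coords:
        t = tuple(c)
        if n_lesions and dt[t] <= match_mm:
            lesion = int(lesion_labels[tuple(indices[:, c[0], c[1], c[2]])])
            if lesion in seen:
                continue
            seen.add(lesion)
            retained.append(c)
            is_tp.append(True)
            ids.append(lesion)
        else:
            retained.append(c)
            is_tp.append(False)
            ids.append(-1)
    retained = np.asarray(retained, dtype=int).reshape(-1, 3)
    is_tp = np.asarray(is_tp, dtype=bool)
    ids = np.asarray(ids, dtype=int)
    probs = prob[tuple(retained.T)] if len(retained) else np.empty(0)

    sensitivity = {}
    for op in fp_operating_points:
        best = 0.0
        fp = 0
        hit = set()
        for flag, lesion in zip(is_tp, ids):
            if flag:
                hit.add(lesion)
            else:
                fp += 1
                if fp > op:
                    break
            if n_lesions:
                best = max(best, len(hit) / n_lesions)
        sensitivity[float(op)] = best
    return DetectionResult(retained, probs, is_tp, ids, int(n_lesions),
                           sensitivity)
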