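"""Synthetic MRI phantoms with concentric zonal anatomy.

Each phantom patient is a small T2w-like volume containing an elliptical
gland whose interior splits into a transition zone (TZ) and a posterior
crescent-shaped peripheral zone (PZ) that partially surrounds it, the PZ
brighter than the TZ as on T2-weighted MRI.  Zones shrink toward the
first and last gland-bearing slices (apex/base thinning) and slices
beyond the gland extent are pure background.  The corruptions the
segmentation method is meant to withstand are applied on top: additive
Gaussian noise, a smooth multiplicative bias field (second-order 2D
polynomial), and a global per-patient intensity scale/shift.

Everything is deterministic given the seed, so phantoms double as test
fixtures that never touch the network.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class PhantomParams:
    image_size: int = 64
    n_slices: int = 8
    spacing: tuple = (3.0, 0.625, 0.625)  # (through-plane, in-plane, in-plane) mm
    #: gland semi-axes as a fraction of the image size
    gland_axis_range: tuple = (0.26, 0.34)
    #: TZ semi-axes as a fraction of the gland semi-axes
    tz_fraction_range: tuple = (0.55, 0.7)
    #: gland-bearing slice count (leaves background-only slices at 8 slices)
    gland_slices_range: tuple = (5, 7)
    center_jitter: float = 0.06           # fraction of image size
    intensity_means: tuple = (0.2, 0.5, 0.85)   # background, TZ, PZ
    noise_std: float = 0.05
    bias_field_amplitude: float = 0.15
    intensity_shift: float = 0.1          # per-patient scale/shift half-range
    rician_noise: bool = False
    n_lesions_range: tuple = (1, 2)
    lesion_radius_mm: tuple = (2.5, 5.0)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16 or self.n_slices < 1:
            raise ValueError("phantom geometry too small")
        if max(self.gland_axis_range) >= 0.5 - self.center_jitter:
            raise ValueError("gland geometry can exceed image bounds")
        if self.gland_slices_range[1] > self.n_slices:
            raise ValueError("gland extent exceeds slice count")


@dataclass
class PhantomPatient:
    volume: np.ndarray        # (S, H, W) float32 intensities
    mask: np.ndarray          # (S, H, W) uint8 labels {0 bg, 1 TZ, 2 PZ}
    lesions: np.ndarray | None
    spacing: tuple
    seed: int
    params: PhantomParams = field(repr=False)


def _bias_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """1 + amplitude * random second-order polynomial, normalised to [-1, 1]."""
    if amplitude == 0:
        return np.ones((size, size))
    y, x = np.meshgrid(np.linspace(-1, 1, size), np.linspace(-1, 1, size),
                       indexing="ij")
    coeffs = rng.normal(size=6)
    poly = (coeffs[0] * x + coeffs[1] * y + coeffs[2] * x * y
            + coeffs[3] * x ** 2 + coeffs[4] * y ** 2 + coeffs[5])
    poly = poly / max(np.abs(poly).max(), 1e-9)
    return 1.0 + amplitude * poly


def generate_phantom(params: PhantomParams, seed: int | None = None) -> PhantomPatient:
    """One deterministic phantom patient."""
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    size, n_slices = params.image_size, params.n_slices
    half = size / 2.0

    a_g = rng.uniform(*params.gland_axis_range) * size   # vertical semi-axis
    b_g = rng.uniform(*params.gland_axis_range) * size   # horizontal semi-axis
    tz_f = rng.uniform(*params.tz_fraction_range)
    ci = half + rng.uniform(-1, 1) * params.center_jitter * size
    cj = half + rng.uniform(-1, 1) * params.center_jitter * size
    n_gland = int(rng.integers(params.gland_slices_range[0],
                               params.gland_slices_range[1] + 1))
    first = (n_slices - n_gland) // 2

    ii, jj = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    mask = np.zeros((n_slices, size, size), dtype=np.uint8)
    for s in range(n_gland):
        # through-plane ellipsoid profile: zones thin toward apex and base
        t = (s - (n_gland - 1) / 2.0) / (n_gland / 2.0 + 0.3)
        scale = np.sqrt(max(1.0 - t * t, 0.05))
        ag, bg = a_g * scale, b_g * scale
        atz, btz = ag * tz_f, bg * tz_f
        # TZ sits anteriorly (smaller i), so the leftover gland ring is a
        # posterior crescent that partially surrounds it
        tz_ci = ci - 0.85 * (ag - atz)
        gland = ((ii - ci) / ag) ** 2 + ((jj - cj) / bg) ** 2 <= 1.0
        tz = ((ii - tz_ci) / atz) ** 2 + ((jj - cj) / btz) ** 2 <= 1.0
        sl = mask[first + s]
        sl[gland] = 2          # PZ = gland minus TZ
        sl[gland & tz] = 1

    means = np.asarray(params.intensity_means)
    volume = means[mask].astype(np.float64)
    if params.bias_field_amplitude:
        bias = _bias_field(size, params.bias_field_amplitude, rng)
        volume = volume * bias[None]
    scale = 1.0 + rng.uniform(-1, 1) * params.intensity_shift
    shift = rng.uniform(-1, 1) * params.intensity_shift
    volume = volume * scale + shift
    if params.noise_std:
        if params.rician_noise:
            nr = rng.normal(0, params.noise_std, volume.shape)
            ni = rng.normal(0, params.noise_std, volume.shape)
            volume = np.sqrt((volume + nr) ** 2 + ni ** 2)
        else:
            volume = volume + rng.normal(0, params.noise_std, volume.shape)

    lesions = _sample_lesions(mask, params, rng)
    return PhantomPatient(volume.astype(np.float32), mask, lesions,
                          tuple(params.spacing), seed, params)


def _sample_lesions(mask: np.ndarray, params: PhantomParams,
                    rng: np.random.Generator) -> np.ndarray | None:
    fg = np.argwhere(mask > 0)
    if fg.size == 0:
        return None
    n = int(rng.integers(params.n_lesions_range[0], params.n_lesions_range[1] + 1))
    spacing = np.asarray(params.spacing)
    grid = np.stack(np.meshgrid(*[np.arange(d) for d in mask.shape],
                                indexing="ij"), axis=-1)
    lesions = np.zeros(mask.shape, dtype=np.uint8)
    for _ in range(n):
        center = fg[rng.integers(len(fg))]
        radius = rng.uniform(*params.lesion_radius_mm)
        dist = np.sqrt((((grid - center) * spacing) ** 2).sum(-1))
        lesions[(dist <= radius) & (mask > 0)] = 1
    return lesions


def generate_dataset(n_patients: int, params: PhantomParams, seed: int = 0,
                     fractions: tuple = (0.75, 0.125, 0.125)) -> dict:
    """Disjoint {train, val, test} patient lists with derived per-patient seeds."""
    if n_patients < 3:
        raise ValueError("need at least 3 patients for a train/val/test split")
    rng = np.random.default_rng(seed)
    patient_seeds = rng.integers(0, 2 ** 31 - 1, size=n_patients)
    n_val = max(1, int(round(fractions[1] * n_patients)))
    n_test = max(1, int(round(fractions[2] * n_patients)))
    n_train = n_patients - n_val - n_test
    if n_train < 1:
        raise ValueError("split fractions leave no training patients")
    patients = [generate_phantom(params, int(s)) for s in patient_seeds]
    return {
        "train": patients[:n_train],
        "val": patients[n_train:n_train + n_val],
        "test": patients[n_train + n_val:],
    }


# ---------------------------------------------------------------------
# detection fixture
# ---------------------------------------------------------------------

@dataclass
class DetectionFixture:
    probability_map: np.ndarray
    lesion_mask: np.ndarray
    spacing: tuple
    peak_voxels: list          # planted peak coordinates, rank order
    expected_tp: list          # parallel booleans


def generate_detection_fixture(params: PhantomParams | None = None) -> DetectionFixture:
    """Probability peaks planted at known physical distances from lesions.

    Two spherical lesions; two peaks inside/within 5 mm of a lesion
    (expected true positives) and two peaks more than 5 mm from every
    lesion voxel (expected false positives).
    """
    params = params or PhantomParams()
    shape = (params.n_slices, params.image_size, params.image_size)
    spacing = np.asarray(params.spacing)
    grid = np.stack(np.meshgrid(*[np.arange(d) for d in shape],
                                indexing="ij"), axis=-1)

    lesions = np.zeros(shape, dtype=np.uint8)
    for center, radius in (((3, 20, 20), 3.0), ((5, 44, 44), 3.0)):
        dist = np.sqrt((((grid - np.asarray(center)) * spacing) ** 2).sum(-1))
        lesions[dist <= radius] = 1

    # (voxel, peak value, expected label); in-plane voxel = 0.625 mm
    plan = [
        ((3, 20, 20), 0.90, True),    # at a lesion centre: 0 mm
        ((5, 44, 50), 0.80, True),    # 6 voxels = 3.75 mm from centre, < 5 mm
        ((3, 20, 52), 0.60, False),   # 32 voxels = 20 mm from lesion 1
        ((6, 10, 44), 0.40, False),   # far from both lesions
    ]
    prob = np.zeros(shape)
    for voxel, peak, _ in plan:
        dist = np.sqrt((((grid - np.asarray(voxel)) * spacing) ** 2).sum(-1))
        prob = np.maximum(prob, peak * np.exp(-(dist ** 2) / (2 * 1.5 ** 2)))
    return DetectionFixture(prob, lesions, tuple(params.spacing),
                            [v for v, _, _ in plan], [t for _, _, t in plan])


# ---------------------------------------------------------------------
# straw-man segmenter (corruption sanity checks)
# ---------------------------------------------------------------------

def threshold_segment(volume: np.ndarray,
                      means: tuple = (0.2, 0.5, 0.85)) -> np.ndarray:
    """Nearest-intensity-level labelling after min-max rescaling."""
    v = np.asarray(volume, dtype=float)
    v = (v - v.min()) / max(v.max() - v.min(), 1e-9)
    levels = (np.asarray(means) - min(means)) / (max(means) - min(means))
    dist = np.abs(v[..., None] - levels)
    return np.argmin(dist, axis=-1).astype(np.uint8)


# ---------------------------------------------------------------------
# NIfTI + manifest persistence
# ---------------------------------------------------------------------

def _affine(spacing: tuple) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_patient(patient: PhantomPatient, directory, name: str) -> dict:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = {"name": name, "seed": int(patient.seed),
               "spacing": list(patient.spacing)}
    affine = _affine(patient.spacing)
    nib.save(nib.Nifti1Image(patient.volume.astype(np.float32), affine),
             directory / f"{name}_image.nii")
    nib.save(nib.Nifti1Image(patient.mask.astype(np.uint8), affine),
             directory / f"{name}_mask.nii")
    if patient.lesions is not None:
        nib.save(nib.Nifti1Image(patient.lesions.astype(np.uint8), affine),
                 directory / f"{name}_lesions.nii")
        entries["lesions"] = f"{name}_lesions.nii"
    entries["image"] = f"{name}_image.nii"
    entries["mask"] = f"{name}_mask.nii"
    return entries


def load_patient(directory, entry: dict, params: PhantomParams | None = None) -> PhantomPatient:
    directory = Path(directory)
    volume = np.asanyarray(nib.load(directory / entry["image"]).dataobj,
                           dtype=np.float32)
    mask = np.asanyarray(nib.load(directory / entry["mask"]).dataobj,
                         dtype=np.uint8)
    lesions = None
    if "lesions" in entry:
        lesions = np.asanyarray(nib.load(directory / entry["lesions"]).dataobj,
                                dtype=np.uint8)
    return PhantomPatient(volume, mask, lesions, tuple(entry["spacing"]),
                          entry["seed"], params or PhantomParams())


def save_dataset(dataset: dict, directory, params: PhantomParams,
                 seed: int) -> Path:
    """Write NIfTI volumes plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    manifest = {"seed": int(seed),
                "params": dataclasses.asdict(params),
                "splits": {}}
    for split, patients in dataset.items():
        manifest["splits"][split] = [
            save_patient(p, directory / split, f"patient{idx:03d}")
            for idx, p in enumerate(patients)]
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_dataset(directory) -> dict:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    params = PhantomParams(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in manifest["params"].items()})
    return {split: [load_patient(directory / split, e, params) for e in entries]
            for split, entries in manifest["splits"].items()}
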