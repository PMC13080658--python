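"""Training-pair preparation and tolerance-aware segmentation metrics.

Prepares microscopy-ground-truth / MRI image pairs for an external 2D
segmentation network (resampling to the 25×25×100 µm evaluation grid,
30 µm diameter filtering, binarization, paired augmentation, subject-grouped
k-fold splits) and evaluates predictions with the Dilated Dice coefficient
and the mean absolute surface distance (MASD), both defined over voxel
centers in world µm.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, GeometryError, Volume, same_grid

__all__ = [
    "SegPair",
    "FoldAssignment",
    "binarize",
    "prep_training_pairs",
    "export_training_pairs",
    "crossval_split",
    "dilated_dice",
    "masd",
    "visibility_transitions",
    "vessel_diameter_from_mask",
    "VISIBILITY_CATEGORIES",
]


@dataclass
class SegPair:
    """Ground truth A (microscopy) and prediction B on one shared grid."""

    truth: BinaryMask
    prediction: BinaryMask

    def __post_init__(self):
        if not same_grid(self.truth, self.prediction):
            raise GeometryError("ground truth and prediction grids differ")


def binarize(prob: Volume, threshold: float) -> BinaryMask:
    """Threshold a probability/intensity map: voxel true ⇔ value ≥ threshold.

    Thresholds are in raw map units (e.g. 10000 for 16-bit probability
    maps)."""
    return BinaryMask(np.asarray(prob.data) >= threshold, prob.spacing, prob.origin)


# ---------------------------------------------------------------------------
# Tolerance-aware metrics

def _dilate_world(mask: np.ndarray, spacing, tolerance: float) -> np.ndarray:
    """World-metric dilation by a ball: voxel included iff its center lies
    within ``tolerance`` µm of a foreground voxel center."""
    if tolerance <= 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= tolerance + 1e-9


def dilated_dice(pair: SegPair, tolerance: float = 50.0) -> float:
    """Dilated Dice coefficient with spatial tolerance (µm).

    DD = (|A ∩ D(B)| + |D(A) ∩ B|) / (|A| + |B|), where D dilates a mask by
    a ball of radius ``tolerance`` in world units, crediting matches within
    that distance (compensating residual registration error).  DD(A, A) = 1;
    tolerance 0 reduces to the plain Dice coefficient.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be ≥ 0")
    a = pair.truth.data
    b = pair.prediction.data
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dilated Dice undefined for two empty masks")
    spacing = pair.truth.spacing
    da = _dilate_world(a, spacing, tolerance)
    db = _dilate_world(b, spacing, tolerance)
    return float((np.sum(a & db) + np.sum(da & b)) / (na + nb))


def masd(pair: SegPair) -> float:
    """Mean absolute surface distance (µm).

    MASD = (Σ_{a∈A} d(a, B) + Σ_{b∈B} d(b, A)) / (|A| + |B|) with Euclidean
    world distances between voxel centers, over *all* foreground voxels (the
    stated symbol definitions), not surface voxels only.  Symmetric;
    MASD(A, A) = 0.
    """
    a = pair.truth.data
    b = pair.prediction.data
    if not a.any() or not b.any():
        raise ValueError("MASD needs both masks nonempty")
    spacing = pair.truth.spacing
    d_to_b = ndimage.distance_transform_edt(~b, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~a, sampling=spacing)
    total = d_to_b[a].sum() + d_to_a[b].sum()
    return float(total / (a.sum() + b.sum()))


def surface_masd(pair: SegPair) -> float:
    """Conventional ASSD variant restricted to surface voxels, for
    comparison with the all-voxel definition used by :func:`masd`."""
    a = pair.truth.data
    b = pair.prediction.data
    if not a.any() or not b.any():
        raise ValueError("surface MASD needs both masks nonempty")

    def _surface(m):
        eroded = ndimage.binary_erosion(m)
        return m & ~eroded

    sa, sb = _surface(a), _surface(b)
    spacing = pair.truth.spacing
    d_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    d_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return float((d_to_b[sa].sum() + d_to_a[sb].sum()) / (sa.sum() + sb.sum()))


# ---------------------------------------------------------------------------
# Cross-validation folds

@dataclass
class FoldAssignment:
    """Dataset-id → fold-index map, grouped so one subject never spans
    folds."""

    assignment: dict
    k: int
    seed: int

    def fold_of(self, dataset_id) -> int:
        return self.assignment[dataset_id]

    def folds(self) -> list[list]:
        out = [[] for _ in range(self.k)]
        for ds, f in self.assignment.items():
            out[f].append(ds)
        return out


def crossval_split(dataset_ids, k: int = 5, seed: int = 0, group_by=None) -> FoldAssignment:
    """Deterministic k-fold split of dataset ids.

    ``group_by`` maps each dataset id to its subject (animal); all datasets
    of one subject land in the same fold, preventing leakage between
    training and validation.  Subject counts per fold differ by at most 1.
    """
    ids = list(dataset_ids)
    if group_by is None:
        group_by = {d: d for d in ids}
    subjects = sorted({group_by[d] for d in ids}, key=str)
    if len(subjects) < k:
        raise ValueError(f"need ≥ {k} subjects for {k}-fold CV, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    subject_fold = {subjects[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment({d: subject_fold[group_by[d]] for d in ids}, k, seed)


# ---------------------------------------------------------------------------
# Training-pair preparation

@dataclass
class TrainingPair:
    image: np.ndarray  # 2D slice
    label: np.ndarray  # 2D boolean
    case_id: str
    spacing: tuple  # (z, y, x) µm of the source grid


def prep_training_pairs(
    image: Volume,
    label_mask: BinaryMask,
    target_spacing=(100.0, 25.0, 25.0),
    min_diameter: float = 30.0,
    crop_size: int | None = None,
    n_crops: int = 1,
    augment: bool = True,
    n_augment: int = 4,
    seed: int = 0,
    registered: bool = True,
) -> list[TrainingPair]:
    """Emit 2D image/label slice pairs for an external segmentation trainer.

    The registered image (MRI frame) and its microscopy label mask are
    resampled to ``target_spacing`` (default 25 µm in-plane, 100 µm slices),
    the label is filtered to vessels of ≥ ``min_diameter`` µm local diameter
    and binarized, and random flips / 90° rotations are applied identically
    to image and label.  Deterministic under ``seed``.
    """
    if not registered:
        raise ValueError("inputs must be registered to a common frame first")
    from .registration import resample_to_spacing
    from .vessels import filter_by_diameter

    rng = np.random.default_rng(seed)
    image_r = resample_to_spacing(image, target_spacing, "linear")
    label_r = resample_to_spacing(label_mask, target_spacing, "nearest")
    if min_diameter > 0 and label_r.data.any():
        label_r = filter_by_diameter(label_r, min_diameter)

    pairs: list[TrainingPair] = []
    case = 0
    for z in range(image_r.shape[0]):
        img2d = np.asarray(image_r.data[z], dtype=float)
        lab2d = label_r.data[z]
        crops = [(slice(None), slice(None))]
        if crop_size is not None and min(img2d.shape) > crop_size:
            crops = []
            for _ in range(n_crops):
                oy = int(rng.integers(0, img2d.shape[0] - crop_size + 1))
                ox = int(rng.integers(0, img2d.shape[1] - crop_size + 1))
                crops.append((slice(oy, oy + crop_size), slice(ox, ox + crop_size)))
        for window in crops:
            base_img = img2d[window]
            base_lab = lab2d[window]
            variants = [(base_img, base_lab)]
            if augment:
                for _ in range(n_augment):
                    gi, gl = base_img, base_lab
                    if rng.random() < 0.5:
                        gi, gl = gi[::-1], gl[::-1]
                    if rng.random() < 0.5:
                        gi, gl = gi[:, ::-1], gl[:, ::-1]
                    rot = int(rng.integers(0, 4))
                    gi, gl = np.rot90(gi, rot), np.rot90(gl, rot)
                    variants.append((gi, gl))
            for gi, gl in variants:
                pairs.append(
                    TrainingPair(
                        gi.copy(), gl.copy(), f"CASE_{case:04d}",
                        tuple(image_r.spacing),
                    )
                )
                case += 1
    return pairs


def export_training_pairs(pairs, out_dir) -> None:
    """Write pairs as paired NIfTI files in the ``imagesTr``/``labelsTr``
    layout expected by standard 2D U-Net trainers (``CASE_xxxx_0000``)."""
    from .io import write_volume

    images = os.path.join(out_dir, "imagesTr")
    labels = os.path.join(out_dir, "labelsTr")
    os.makedirs(images, exist_ok=True)
    os.makedirs(labels, exist_ok=True)
    for p in pairs:
        sp = (p.spacing[0], p.spacing[1], p.spacing[2])
        img = Volume(p.image[None], sp)
        lab = Volume(p.label[None].astype(np.uint8), sp)
        write_volume(img, os.path.join(images, f"{p.case_id}_0000.nii.gz"))
        write_volume(lab, os.path.join(labels, f"{p.case_id}.nii.gz"))


# ---------------------------------------------------------------------------
# Vessel-level comparisons

VISIBILITY_CATEGORIES = ("strongly visible", "barely visible", "not visible")


def visibility_transitions(
    labels_before, labels_after, categories=VISIBILITY_CATEGORIES
) -> pd.DataFrame:
    """Per-vessel visibility transition counts (rows = before, columns =
    after); the matrix total equals the vessel count."""
    before = list(labels_before)
    after = list(labels_after)
    if len(before) != len(after):
        raise ValueError("label lists must cover the same vessels")
    for lab in before + after:
        if lab not in categories:
            raise ValueError(f"unknown visibility label {lab!r}")
    matrix = pd.DataFrame(
        0, index=list(categories), columns=list(categories), dtype=int
    )
    for b, a in zip(before, after):
        matrix.loc[b, a] += 1
    return matrix


def vessel_diameter_from_mask(mask: BinaryMask, probe_point) -> float:
    """Local vessel diameter (µm) at a world-coordinate probe point.

    Restricted to the connected component containing the probe, then read
    from the local-thickness map at the probe voxel.
    """
    from .vessels import estimate_local_diameter

    idx = np.rint(mask.world_to_index(probe_point)).astype(int).ravel()
    if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
        raise ValueError("probe point outside the mask volume")
    if not mask.data[tuple(idx)]:
        raise ValueError("probe point lies in background")
    labeled, _ = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    component = labeled == labeled[tuple(idx)]
    thickness = estimate_local_diameter(
        BinaryMask(component, mask.spacing, mask.origin)
    )
    return float(thickness.data[tuple(idx)])
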