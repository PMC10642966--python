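"""Label propagation between samples through unfolded-space transforms.

Subfield labels travel from each sample to the reference through the
groupwise template: reference pixel -> template (inverse of the
reference's warp) -> sample (the sample's warp), sampled nearest-neighbor
(labels are categorical, never blended).  Unfolded labels are then
projected full-thickness into the reference's native gray matter via its
unfolding coordinates.  The no-registration baseline is the same
propagation with identity transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import LabelVolume, UnfoldedMap
from .registration import DiffeoTransform, compose, invert
from .unfolding import CoordinateFields


@dataclass
class PropagationResult:
    unfolded: UnfoldedMap
    native: LabelVolume | None = None
    n_imputed: int = 0


def propagate_labels_unfolded(labels_i: UnfoldedMap, t_i: DiffeoTransform,
                              t_ref: DiffeoTransform) -> UnfoldedMap:
    """Carry sample i's unfolded labels into the reference's unfolded space.

    ``t_i`` and ``t_ref`` are the template-building transforms (point maps
    template -> sample, i.e. the warps that pull each sample onto the
    template).  Each reference pixel is mapped template-ward through the
    inverse of ``t_ref``, then sample-ward through ``t_i``, and the label
    is read nearest-neighbor.
    """
    if labels_i.shape != t_i.shape or t_i.shape != t_ref.shape:
        raise ValueError(
            f"grid mismatch: labels {labels_i.shape}, t_i {t_i.shape}, "
            f"t_ref {t_ref.shape}")
    total = compose(invert(t_ref), t_i)  # ref -> template -> sample i
    # supersampled majority vote: nearest sampling at 3x3 sub-pixel
    # offsets removes single-pixel aliasing islands at label boundaries
    # while keeping labels categorical
    shape = labels_i.shape
    vals = np.asarray(labels_i.values)
    base = np.stack(np.meshgrid(np.arange(shape[0], dtype=float),
                                np.arange(shape[1], dtype=float),
                                indexing="ij"), axis=0)
    n_lab = int(vals.max()) + 1
    votes = np.zeros(shape + (max(n_lab, 1),), dtype=np.int16)
    for da in (-1 / 3, 0.0, 1 / 3):
        for dp in (-1 / 3, 0.0, 1 / 3):
            pts = (base + np.array([da, dp])[:, None, None]).reshape(2, -1).T
            mapped = total.map_points(pts)
            sampled = ndimage.map_coordinates(vals.astype(float), mapped.T,
                                              order=0, mode="nearest")
            sampled = np.rint(sampled).astype(int).reshape(shape)
            np.add.at(votes.reshape(-1, votes.shape[-1]),
                      (np.arange(vals.size), sampled.ravel()), 1)
    out = np.argmax(votes, axis=-1).astype(vals.dtype)  # ties: smaller id
    return UnfoldedMap(values=out, spacing=labels_i.spacing,
                       channel=labels_i.channel, units=labels_i.units)


def project_to_native(ref_coords: CoordinateFields,
                      unfolded_labels: UnfoldedMap,
                      ref_vol: LabelVolume) -> tuple[LabelVolume, int]:
    """Project unfolded labels into the reference's native gray matter.

    Every gray-matter voxel takes the label of the unfolded pixel at its
    (ap, pd) coordinate (whole laminar columns share one label: subfields
    are full-thickness parcels).  Returns the labeled volume and the count
    of gray voxels with missing coordinates (left 0 for later imputation).
    """
    shape = ref_vol.voxels.shape
    out = np.zeros(shape, dtype=np.int16)
    gray = ref_coords.mask
    ap = ref_coords.ap[gray]
    pd = ref_coords.pd[gray]
    ok = np.isfinite(ap) & np.isfinite(pd)
    na, npd = unfolded_labels.shape
    ia = np.clip((ap[ok] * na).astype(int), 0, na - 1)
    ip = np.clip((pd[ok] * npd).astype(int), 0, npd - 1)
    vals = np.zeros(gray.sum(), dtype=np.int16)
    vals[ok] = np.asarray(unfolded_labels.values)[ia, ip]
    out[gray] = vals
    n_missing = int((~ok).sum())
    return LabelVolume(out, np.asarray(ref_vol.affine)), n_missing


def impute_missing(label_map: UnfoldedMap) -> tuple[UnfoldedMap, int]:
    """Fill zero pixels with the nearest (unfolded mm) non-zero label.

    At exactly equal distance the smaller label id wins, which makes the
    result independent of scan order.
    """
    vals = np.asarray(label_map.values)
    if not (vals != 0).any():
        raise ValueError("cannot impute an all-zero label map")
    missing = vals == 0
    n = int(missing.sum())
    if n == 0:
        return UnfoldedMap(vals.copy(), label_map.spacing,
                           label_map.channel, label_map.units), 0
    present = sorted(int(l) for l in np.unique(vals) if l != 0)
    dists = np.stack([
        ndimage.distance_transform_edt(vals != lab,
                                       sampling=label_map.spacing)
        for lab in present])
    # argmin returns the first (smallest-id) label on ties
    nearest = np.asarray(present, dtype=np.int16)[np.argmin(dists, axis=0)]
    out = vals.copy()
    out[missing] = nearest[missing]
    return UnfoldedMap(out, label_map.spacing, label_map.channel,
                       label_map.units), n


def flip_lr(vol: LabelVolume) -> LabelVolume:
    """Mirror about the world sagittal plane (x = 0).

    Only the affine changes (world handedness flips); voxel data and
    labels are untouched, so flipping twice is an exact identity.
    """
    F = np.diag([-1.0, 1.0, 1.0, 1.0])
    return LabelVolume(vol.voxels.copy(), F @ np.asarray(vol.affine))
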