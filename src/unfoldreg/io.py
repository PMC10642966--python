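"""Reading and writing of label volumes, unfolded maps, and transforms.

3D volumes are NIfTI-1.  Unfolded 2D maps are stored as degenerate
third-axis NIfTI (so standard viewers open them) with a JSON sidecar
holding grid metadata.  Transforms are multi-component NIfTI plus a JSON
sidecar describing kind, dimensionality and domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

# Label scheme for hippocampal segmentations.
BG = 0
SUB = 1
CA1 = 2
CA2 = 3
CA3 = 4
CA4 = 5  # includes the dentate gyrus
SRLM = 6
ANTERIOR = 7
POSTERIOR = 8
PROXIMAL = 9
DISTAL = 10

GRAY_LABELS = (SUB, CA1, CA2, CA3, CA4)
SUBFIELD_NAMES = {SUB: "Sub", CA1: "CA1", CA2: "CA2", CA3: "CA3", CA4: "CA4"}
ALL_LABELS = tuple(range(11))

#: physical extent of the unfolded rectangle in mm (A-P, P-D); gives the
#: default 256 x 128 grid square 0.15625 mm pixels.
UNFOLDED_EXTENT_MM = (40.0, 20.0)
DEFAULT_GRID = (256, 128)


def unfolded_spacing(shape: tuple[int, int],
                     extent_mm: tuple[float, float] = UNFOLDED_EXTENT_MM
                     ) -> tuple[float, float]:
    """Pixel spacing (mm) of an unfolded grid of the given shape."""
    return (extent_mm[0] / shape[0], extent_mm[1] / shape[1])


@dataclass
class LabelVolume:
    """3D integer labelmap with a voxel-to-world affine (mm)."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.voxels.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (always positive)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def gray_mask(self) -> np.ndarray:
        return (self.voxels >= SUB) & (self.voxels <= CA4)

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_coords(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world mm coordinates to fractional voxel indices."""
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class UnfoldedMap:
    """2D map over the unfolded rectangle (rows = A-P, cols = P-D)."""

    values: np.ndarray
    spacing: tuple[float, float] = unfolded_spacing(DEFAULT_GRID)
    channel: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"expected 2D map, got {self.values.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing[0] * self.spacing[1]


@dataclass
class TransformRecord:
    """Serializable record of a rigid or diffeomorphic transform.

    ``parameters`` holds either ``{"matrix": 3x3, "translation": 3}``
    (rigid, pulling fixed-world points into moving-world) or dense
    displacement component arrays for a diffeomorphism.
    """

    kind: str  # "rigid" | "diffeo"
    dim: int
    parameters: dict

    def __post_init__(self) -> None:
        if self.kind not in ("rigid", "diffeo"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.dim not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")


# ---------------------------------------------------------------------------
# volumes

def read_volume(path, labels: bool = True) -> LabelVolume:
    """Read a 3D NIfTI image as a :class:`LabelVolume`.

    With ``labels=True`` the data must be integer-valued; a float image
    whose values are not whole numbers raises a ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D: {path}")
    if labels:
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise ValueError(
                    f"label volume has non-integer data (dtype {data.dtype}): {path}")
            data = rounded.astype(np.int16)
        else:
            data = data.astype(np.int16, copy=False)
    return LabelVolume(voxels=data, affine=np.asarray(img.affine))


def write_volume(vol: LabelVolume | np.ndarray, path, affine=None) -> None:
    """Write a labelmap or scalar volume to NIfTI."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    if isinstance(vol, LabelVolume):
        data, aff = vol.voxels, vol.affine
    else:
        data = np.asarray(vol)
        aff = np.eye(4) if affine is None else np.asarray(affine)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16, copy=False)
    else:
        data = data.astype(np.float32, copy=False)
    nib.save(nib.Nifti1Image(data, aff), str(path))


# ---------------------------------------------------------------------------
# unfolded maps and transforms

def _sidecar(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_unfolded(obj: UnfoldedMap | TransformRecord, path) -> None:
    """Write an unfolded map or transform record (NIfTI + JSON sidecar)."""
    path = Path(path)
    if isinstance(obj, UnfoldedMap):
        data = np.asarray(obj.values)[:, :, None].astype(
            np.int16 if np.issubdtype(obj.values.dtype, np.integer) else np.float32)
        aff = np.diag([obj.spacing[0], obj.spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(data, aff), str(path))
        meta = {"type": "unfolded_map", "shape": list(obj.values.shape),
                "spacing": list(obj.spacing), "channel": obj.channel,
                "units": obj.units,
                "integer": bool(np.issubdtype(obj.values.dtype, np.integer))}
    elif isinstance(obj, TransformRecord):
        params = obj.parameters
        meta = {"type": "transform", "kind": obj.kind, "dim": obj.dim}
        if obj.kind == "rigid":
            meta["matrix"] = np.asarray(params["matrix"]).tolist()
            meta["translation"] = np.asarray(params["translation"]).tolist()
            nib.save(nib.Nifti1Image(np.zeros((1, 1, 1), np.float32), np.eye(4)),
                     str(path))
        else:
            comps = np.asarray(params["displacement"], dtype=np.float32)
            # components stacked on the last axis; pad 2D fields to 3D images
            if obj.dim == 2:
                data = comps.transpose(1, 2, 0)[:, :, None, :]
            else:
                data = comps.transpose(1, 2, 3, 0)
            nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
            meta["grid"] = list(comps.shape[1:])
            meta["spacing"] = list(params.get("spacing", [1.0] * obj.dim))
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_unfolded(path) -> UnfoldedMap | TransformRecord:
    """Inverse of :func:`write_unfolded`."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    if meta["type"] == "unfolded_map":
        data = np.asanyarray(nib.load(str(path)).dataobj)[:, :, 0]
        if meta.get("integer"):
            data = np.rint(data).astype(np.int16)
        return UnfoldedMap(values=data, spacing=tuple(meta["spacing"]),
                           channel=meta.get("channel", ""),
                           units=meta.get("units", ""))
    if meta["type"] == "transform":
        if meta["kind"] == "rigid":
            params = {"matrix": np.asarray(meta["matrix"]),
                      "translation": np.asarray(meta["translation"])}
            return TransformRecord("rigid", meta["dim"], params)
        data = np.asanyarray(nib.load(str(path)).dataobj)
        dim = meta["dim"]
        if dim == 2:
            comps = data[:, :, 0, :].transpose(2, 0, 1)
        else:
            comps = data.transpose(3, 0, 1, 2)
        return TransformRecord("diffeo", dim,
                               {"displacement": comps.astype(np.float64),
                                "spacing": meta.get("spacing")})
    raise ValueError(f"unknown sidecar type {meta['type']!r}")
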