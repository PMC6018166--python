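"""Volume I/O, brain-box cropping, per-view slice decomposition and grouping.

A 3D intensity volume is classified by decomposing it along one of the three
anatomical viewing directions (sagittal, coronal, axial) into an ordered
sequence of 2D slices.  Slices are partitioned into overlapping groups (by
default 15 slices per group, stride 9, hence 6 shared slices between
neighbouring groups); each group later gets its own 2D convolutional
network.  Slices are reduced to a common in-plane size by centred cropping
(with symmetric zero padding for undersized slices) so that every group
network can share one architecture.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np

VIEWS = ("sagittal", "coronal", "axial")

DEFAULT_VIEW_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


class DimensionError(ValueError):
    """Raised when an image is not three-dimensional."""


class EmptyBrainError(ValueError):
    """Raised when no voxel exceeds the brain threshold."""


@dataclass
class Volume:
    """A 3D non-negative intensity array with voxel spacing and view mapping.

    ``view_axes`` maps each anatomical view name to the array axis along
    which the volume is sliced for that view; it must be a bijection onto
    {0, 1, 2}.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    view_axes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_VIEW_AXES))
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(f"volume must be 3-D, got {self.data.ndim} dimensions")
        if not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")
        if (self.data < 0).any():
            raise ValueError("volume intensities must be non-negative")
        if set(self.view_axes) != set(VIEWS) or sorted(self.view_axes.values()) != [0, 1, 2]:
            raise ValueError("view_axes must map sagittal/coronal/axial onto axes {0,1,2}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SliceStack:
    """Ordered 2D slices of one volume along one view."""

    view: str
    slices: np.ndarray  # (n_slices, H, W)
    index_origin: np.ndarray  # 0-based slice indices in the source volume

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if len(self.slices) != len(self.index_origin):
            raise ValueError("one origin index per slice required")

    def __len__(self) -> int:
        return len(self.slices)


@dataclass
class GroupingScheme:
    """Sliding-window partition of a slice sequence into overlapping groups."""

    group_size: int = 15
    stride: int = 9
    tail_policy: str = "drop_incomplete"

    def __post_init__(self):
        if not (1 <= self.stride <= self.group_size):
            raise ValueError("require 1 <= stride <= group_size")
        if self.tail_policy not in ("drop_incomplete", "anchor_last"):
            raise ValueError(f"unknown tail_policy {self.tail_policy!r}")

    @property
    def overlap(self) -> int:
        return self.group_size - self.stride


@dataclass
class SliceGroup:
    """A window of consecutive slices from one view, cropped to a common size."""

    view: str
    start_index: int
    slices: np.ndarray  # (L, H, W)
    subject_id: str | None = None
    label: int | None = None


def view_axes_from_affine(affine: np.ndarray) -> dict[str, int]:
    """Derive the view-to-axis mapping from a NIfTI affine.

    The axis closest to the left-right anatomical direction is the sagittal
    slicing axis, anterior-posterior the coronal axis, and inferior-superior
    the axial axis.
    """
    codes = nib.orientations.aff2axcodes(affine)
    letter_to_view = {"R": "sagittal", "L": "sagittal", "A": "coronal", "P": "coronal", "S": "axial", "I": "axial"}
    mapping = {letter_to_view[c]: axis for axis, c in enumerate(codes)}
    if len(mapping) != 3:
        return dict(DEFAULT_VIEW_AXES)
    return mapping


def read_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) volume, or the plain .npz fixture format."""
    path = str(path)
    if path.endswith(".npz"):
        with np.load(path) as archive:
            data = archive["data"]
            spacing = tuple(archive["spacing"]) if "spacing" in archive else (1.0, 1.0, 1.0)
        if data.ndim != 3:
            raise DimensionError(f"expected a 3-D array, got {data.ndim} dimensions")
        return Volume(data=data, spacing=spacing)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionError(f"expected a 3-D image, got {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, view_axes=view_axes_from_affine(img.affine), affine=np.asarray(img.affine))


def write_volume(v: Volume, path) -> None:
    path = str(path)
    if path.endswith(".npz"):
        np.savez(path, data=v.data, spacing=np.asarray(v.spacing))
        return
    affine = v.affine if v.affine is not None else np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), path)


def crop_to_brain(v: Volume, threshold: float = 0.0) -> Volume:
    """Crop to the minimal bounding box of voxels with intensity > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = v.data > threshold
    if not mask.any():
        raise EmptyBrainError(f"no voxel above threshold {threshold}")
    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    cropped = v.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    return Volume(data=cropped, spacing=v.spacing, view_axes=dict(v.view_axes), affine=v.affine)


def decompose(v: Volume, view: str) -> SliceStack:
    """Split a volume into ordered 2D slices along the given view axis."""
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
    axis = v.view_axes[view]
    slices = np.moveaxis(v.data, axis, 0)
    return SliceStack(view=view, slices=slices, index_origin=np.arange(slices.shape[0]))


def restack(stack: SliceStack, view_axes: dict[str, int] | None = None) -> np.ndarray:
    """Inverse of :func:`decompose`: reassemble the 3D array from a stack."""
    axes = view_axes if view_axes is not None else DEFAULT_VIEW_AXES
    return np.moveaxis(np.asarray(stack.slices), 0, axes[stack.view])


def center_crop(slice_2d: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Centre-crop (or symmetrically zero-pad) a 2D slice to ``target``.

    When a margin is odd the extra dropped (or padded) row/column is taken
    on the high-index side.
    """
    slice_2d = np.asarray(slice_2d)
    if slice_2d.ndim != 2:
        raise ValueError("expected a 2-D slice")
    th, tw = int(target[0]), int(target[1])
    out = slice_2d
    pads = []
    for size, tsize in zip(out.shape, (th, tw)):
        deficit = max(0, tsize - size)
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, mode="constant")
    h, w = out.shape
    top = (h - th) // 2
    left = (w - tw) // 2
    return out[top : top + th, left : left + tw]


def make_groups(n_slices: int, scheme: GroupingScheme) -> list[int]:
    """Start indices of slice groups under the scheme's tail policy."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    L, s = scheme.group_size, scheme.stride
    starts = list(range(0, n_slices - L + 1, s)) if n_slices >= L else []
    if not starts and scheme.tail_policy == "drop_incomplete":
        warnings.warn(f"{n_slices} slices cannot fill one group of {L}; no groups produced", stacklevel=2)
        return starts
    if scheme.tail_policy == "anchor_last" and n_slices >= L:
        covered = starts[-1] + L if starts else 0
        if covered < n_slices and (n_slices - L) not in starts:
            starts.append(n_slices - L)
    return starts


def extract_groups(
    stack: SliceStack,
    scheme: GroupingScheme,
    crop: tuple[int, int] | None = None,
    subject_id: str | None = None,
    label: int | None = None,
) -> list[SliceGroup]:
    """Cut a slice stack into cropped :class:`SliceGroup` windows."""
    starts = make_groups(len(stack), scheme)
    groups = []
    for start in starts:
        window = stack.slices[start : start + scheme.group_size]
        if crop is not None:
            window = np.stack([center_crop(sl, crop) for sl in window])
        groups.append(
            SliceGroup(view=stack.view, start_index=start, slices=np.asarray(window), subject_id=subject_id, label=label)
        )
    return groups


def save_slice_groups(h5_path, manifest_path, groups: list[SliceGroup], scheme: GroupingScheme) -> None:
    """Persist groups to HDF5 (one dataset per group) plus a JSON manifest."""
    manifest = {"scheme": {"group_size": scheme.group_size, "stride": scheme.stride, "tail_policy": scheme.tail_policy}, "groups": []}
    with h5py.File(h5_path, "w") as f:
        for i, g in enumerate(groups):
            key = f"group_{i:04d}"
            f.create_dataset(key, data=g.slices)
            manifest["groups"].append(
                {"key": key, "view": g.view, "start_index": int(g.start_index), "subject_id": g.subject_id, "label": g.label}
            )
    with open(manifest_path, "w") as f:
        json.dump(manifest, f, indent=1)


def load_slice_groups(h5_path, manifest_path) -> tuple[list[SliceGroup], GroupingScheme]:
    with open(manifest_path) as f:
        manifest = json.load(f)
    scheme = GroupingScheme(**manifest["scheme"])
    groups = []
    with h5py.File(h5_path, "r") as f:
        for entry in manifest["groups"]:
            groups.append(
                SliceGroup(
                    view=entry["view"],
                    start_index=entry["start_index"],
                    slices=f[entry["key"]][()],
                    subject_id=entry["subject_id"],
                    label=entry["label"],
                )
            )
    return groups, scheme
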