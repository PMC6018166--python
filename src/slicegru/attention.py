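"""Occlusion-sensitivity attention maps.

A square patch (default 25x25, fill 0 — a "black" occluder on the
normalised intensity scale) slides over an input slice; at each position
the classifier is re-evaluated and the drop in correct-class probability
is recorded.  Large drops mark regions the classifier relies on.  Maps
from the best-performing slice groups are compiled into an aggregate
attention volume by per-voxel averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class OcclusionConfigError(ValueError):
    pass


@dataclass
class OcclusionConfig:
    square: int = 25
    stride: int = 12
    fill: float = 0.0

    def __post_init__(self):
        if self.square < 1 or self.stride < 1:
            raise OcclusionConfigError("square and stride must be >= 1")


def _positions(extent: int, square: int, stride: int) -> np.ndarray:
    """Top-left offsets on the stride grid, with the border-anchored last position."""
    last = extent - square
    pos = list(range(0, last + 1, stride))
    if pos[-1] != last:
        pos.append(last)  # anchor so the border is covered
    return np.asarray(pos)


@dataclass
class AttentionMap:
    """Probability-drop grid for one slice, with enough provenance to re-embed it."""

    drops: np.ndarray  # (n_row_positions, n_col_positions)
    row_starts: np.ndarray
    col_starts: np.ndarray
    square: int
    slice_shape: tuple[int, int]
    provenance: dict = field(default_factory=dict)  # view, slice_index, offset

    def render(self) -> np.ndarray:
        """Full-resolution map: each pixel takes the drop of the nearest occluder centre."""
        h, w = self.slice_shape
        rc = self.row_starts + self.square / 2.0
        cc = self.col_starts + self.square / 2.0
        ri = np.abs(np.arange(h)[:, None] - rc[None, :]).argmin(axis=1)
        ci = np.abs(np.arange(w)[:, None] - cc[None, :]).argmin(axis=1)
        return self.drops[np.ix_(ri, ci)]


def occlusion_map(
    classifier,
    slice_2d: np.ndarray,
    true_class: int,
    cfg: OcclusionConfig | None = None,
    provenance: dict | None = None,
) -> AttentionMap:
    """Slide the occluder over ``slice_2d`` and record correct-class probability drops.

    ``classifier`` is any callable mapping a 2D slice to a class-probability
    vector.  drop(position) = p_correct(original) - p_correct(occluded).
    """
    cfg = cfg or OcclusionConfig()
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    h, w = slice_2d.shape
    if cfg.square > h or cfg.square > w:
        raise OcclusionConfigError(f"occluder {cfg.square} exceeds slice extent {slice_2d.shape}")
    p0 = float(np.asarray(classifier(slice_2d))[true_class])
    rows = _positions(h, cfg.square, cfg.stride)
    cols = _positions(w, cfg.square, cfg.stride)
    occluded = np.empty((len(rows) * len(cols), h, w))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            sl = slice_2d.copy()
            sl[r : r + cfg.square, c : c + cfg.square] = cfg.fill
            occluded[i * len(cols) + j] = sl
    if getattr(classifier, "accepts_batch", False):
        probs = np.asarray(classifier(occluded))
    else:
        probs = np.stack([np.asarray(classifier(sl)) for sl in occluded])
    drops = (p0 - probs[:, true_class]).reshape(len(rows), len(cols))
    return AttentionMap(
        drops=drops,
        row_starts=rows,
        col_starts=cols,
        square=cfg.square,
        slice_shape=(h, w),
        provenance=dict(provenance or {}),
    )


def select_top_groups(group_val_accuracies: dict[int, float], k: int = 3) -> list[int]:
    """The ``k`` group ids with the best validation accuracy (low id wins ties)."""
    if not group_val_accuracies:
        raise ValueError("no group accuracies given")
    ranked = sorted(group_val_accuracies.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} groups available; requested top {k}", stacklevel=2)
        k = len(ranked)
    return [gid for gid, _ in ranked[:k]]


def compile_attention(
    maps: list[AttentionMap],
    volume_shape: tuple[int, int, int],
    view_axes: dict[str, int],
) -> np.ndarray:
    """Per-voxel mean of rendered drops across contributing slices.

    Each map's provenance must give its ``view``, the 0-based ``slice_index``
    along that view's axis, and the in-plane ``offset`` (top, left) of the
    cropped slice inside the full slice plane (negative when the slice was
    zero-padded).  Voxels never touched by a map stay 0.
    """
    if not maps:
        raise ValueError("no attention maps given")
    total = np.zeros(volume_shape)
    count = np.zeros(volume_shape)
    for m in maps:
        view = m.provenance["view"]
        idx = int(m.provenance["slice_index"])
        top, left = (int(o) for o in m.provenance.get("offset", (0, 0)))
        axis = view_axes[view]
        plane_axes = [a for a in range(3) if a != axis]
        plane_shape = (volume_shape[plane_axes[0]], volume_shape[plane_axes[1]])
        rendered = m.render()
        plane = np.zeros(plane_shape)
        cnt = np.zeros(plane_shape)
        r0, c0 = max(top, 0), max(left, 0)
        mr0, mc0 = r0 - top, c0 - left
        r1 = min(top + rendered.shape[0], plane_shape[0])
        c1 = min(left + rendered.shape[1], plane_shape[1])
        if r1 <= r0 or c1 <= c0:
            continue
        plane[r0:r1, c0:c1] = rendered[mr0 : mr0 + (r1 - r0), mc0 : mc0 + (c1 - c0)]
        cnt[r0:r1, c0:c1] = 1.0
        slicer: list = [slice(None)] * 3
        slicer[axis] = idx
        total[tuple(slicer)] += plane
        count[tuple(slicer)] += cnt
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1e-300), 0.0)
    return out
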