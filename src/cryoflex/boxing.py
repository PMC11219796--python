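"""Box segmentation, screening, normalization and merging.

Maps are cut into 40^3 boxes on a stride-10 lattice so that the 10^3 central
subboxes tile the original grid exactly once (a 15-voxel zero pad surrounds
the map, and the far side is padded up to a multiple of the stride).  Boxes
whose central subbox contains no atom-occupied voxel are screened out; each
retained box records its tile index so subbox predictions can be merged back
into a map with no overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rmsf import RMSFMap
from .voxel import VoxelGrid

__all__ = ["BoxSpec", "SampleBox", "segment_boxes", "normalize_box",
           "merge_subboxes"]


@dataclass(frozen=True)
class BoxSpec:
    """Geometry of the sliding-box decomposition."""

    box_edge: int = 40
    stride: int = 10
    subbox_edge: int = 10

    def __post_init__(self):
        if (self.box_edge - self.subbox_edge) % 2:
            raise ValueError("box and subbox edges must differ by an even margin")
        if self.stride != self.subbox_edge:
            raise ValueError("stride must equal the subbox edge (exact tiling)")

    @property
    def pad(self) -> int:
        """Padding per side so every original voxel lands in one subbox."""
        return (self.box_edge - self.subbox_edge) // 2


@dataclass
class SampleBox:
    """One training/inference unit.

    ``channels``: (C, 40, 40, 40) normalized densities in [0, 1];
    ``label``/``mask``: the 10^3 central subbox RMSF values and labeled-voxel
    mask (label is None at inference); ``grid_index``: tile index (tx, ty, tz)
    such that the subbox covers original voxels ``[t * stride, t * stride + 10)``.
    """

    channels: np.ndarray
    grid_index: tuple[int, int, int]
    label: np.ndarray | None = None
    mask: np.ndarray | None = None
    occupancy: np.ndarray | None = None  # full-box binary truth (classifier)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4:
            raise ValueError("channels must be (C, E, E, E)")


def normalize_box(densities: np.ndarray) -> np.ndarray:
    """Clamp negatives to 0, then divide by the box maximum.

    An all-non-positive box normalizes to all zeros.
    """
    d = np.maximum(np.asarray(densities, dtype=np.float32), 0.0)
    peak = d.max()
    if peak > 0:
        d = d / peak
    return d


def _pad_to_tiling(values: np.ndarray, spec: BoxSpec) -> np.ndarray:
    pad = spec.pad
    extra = [(-s) % spec.stride for s in values.shape]
    widths = [(pad, pad + e) for e in extra]
    return np.pad(values, widths)


def segment_boxes(channels: list[VoxelGrid], labels: RMSFMap | None = None,
                  screen_mask: np.ndarray | None = None,
                  spec: BoxSpec = BoxSpec(),
                  occupancy: VoxelGrid | None = None) -> list[SampleBox]:
    """Cut channel grids into screened, normalized sample boxes.

    Retention: a box is kept iff its central subbox contains at least one
    True voxel of the screening mask — the label mask when ``labels`` is
    given, otherwise ``screen_mask`` (at inference, the model-derived
    occupancy).  Tiles are enumerated in ascending (x, y, z) order.
    """
    if not channels:
        raise ValueError("need at least one channel grid")
    shape = channels[0].shape
    for g in channels[1:]:
        if g.shape != shape:
            raise ValueError("channel grids must share a shape")
    if labels is not None:
        if labels.values.shape != shape:
            raise ValueError("label grid shape must match the channels")
        screen = labels.mask
    elif screen_mask is not None:
        if screen_mask.shape != shape:
            raise ValueError("screen mask shape must match the channels")
        screen = np.asarray(screen_mask, dtype=bool)
    else:
        raise ValueError("either labels or a screening mask is required")

    padded_channels = [_pad_to_tiling(g.values, spec) for g in channels]
    padded_screen = _pad_to_tiling(screen, spec)
    if labels is not None:
        padded_label = _pad_to_tiling(labels.values.values, spec)
    padded_occ = _pad_to_tiling(occupancy.values, spec) if occupancy is not None else None
    n_tiles = [int(np.ceil(s / spec.stride)) for s in shape]
    e, sub, pad = spec.box_edge, spec.subbox_edge, spec.pad

    boxes: list[SampleBox] = []
    for tx in range(n_tiles[0]):
        for ty in range(n_tiles[1]):
            for tz in range(n_tiles[2]):
                a = (tx * spec.stride, ty * spec.stride, tz * spec.stride)
                sub_sl = tuple(slice(ai + pad, ai + pad + sub) for ai in a)
                mask_sub = padded_screen[sub_sl]
                if not mask_sub.any():
                    continue
                box_sl = tuple(slice(ai, ai + e) for ai in a)
                ch = np.stack([normalize_box(pc[box_sl]) for pc in padded_channels])
                label = padded_label[sub_sl].copy() if labels is not None else None
                occ = padded_occ[box_sl].copy() if padded_occ is not None else None
                boxes.append(SampleBox(ch, (tx, ty, tz), label,
                                       mask_sub.copy(), occ))
    return boxes


def merge_subboxes(predictions: list[tuple[tuple[int, int, int], np.ndarray]],
                   grid_shape: tuple[int, int, int],
                   spec: BoxSpec = BoxSpec(),
                   voxel_size: float = 1.5,
                   origin=(0.0, 0.0, 0.0)) -> RMSFMap:
    """Write 10^3 subbox predictions back into a map of ``grid_shape``.

    Tiles never overlap (stride equals the subbox edge); voxels not covered
    by any prediction are 0 with a False mask; tile parts that fall in the
    far-side padding are discarded.
    """
    values = np.zeros(grid_shape, dtype=np.float32)
    mask = np.zeros(grid_shape, dtype=bool)
    seen: set[tuple[int, int, int]] = set()
    sub = spec.subbox_edge
    for index, block in predictions:
        index = tuple(int(i) for i in index)
        if index in seen:
            raise ValueError(f"duplicate tile index {index}")
        seen.add(index)
        block = np.asarray(block, dtype=np.float32)
        if block.shape != (sub,) * 3:
            raise ValueError(f"prediction block must be {sub}^3")
        a = [i * spec.stride for i in index]
        if any(ai < 0 or ai >= s + ((-s) % spec.stride)
               for ai, s in zip(a, grid_shape)):
            raise ValueError(f"tile index {index} outside the grid tiling")
        keep = [min(sub, s - ai) for ai, s in zip(a, grid_shape)]
        if any(k <= 0 for k in keep):
            raise ValueError(f"tile index {index} outside the grid tiling")
        sl = tuple(slice(ai, ai + k) for ai, k in zip(a, keep))
        values[sl] = block[:keep[0], :keep[1], :keep[2]]
        mask[sl] = True
    grid = VoxelGrid(values, voxel_size, np.asarray(origin, float))
    return RMSFMap(grid, mask)
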