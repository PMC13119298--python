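"""Blockwise reconstruction of large volumes: crop, reconstruct, stitch.

Spatio-angular deconvolution of a full acquisition multiplies memory by the
15 SH channels and the modulation count, so large stacks are processed as
overlapping sub-volumes (default 100^3 with 10% overlap per boundary).  The
reconstructed blocks are fused by linear blending with trapezoidal ramps
whose per-voxel weights are normalized to a partition of unity, so constant
inputs stitch without seams and the result is independent of block order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import SHField
from .sphere import N_CHANNELS


@dataclass(frozen=True)
class BlockLayout:
    """Block start positions (per axis) and the common block/overlap shape."""

    shape: tuple[int, int, int]
    block: tuple[int, int, int]
    overlap: tuple[int, int, int]
    starts: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]

    @property
    def blocks(self) -> list[tuple[int, int, int]]:
        out = []
        for z in self.starts[0]:
            for y in self.starts[1]:
                for x in self.starts[2]:
                    out.append((z, y, x))
        return out

    def slices(self, origin: tuple[int, int, int]) -> tuple[slice, slice, slice]:
        return tuple(slice(o, o + b) for o, b in zip(origin, self.block))


def _axis_starts(n: int, block: int, overlap: int) -> tuple[int, ...]:
    if block >= n:
        return (0,)
    step = block - overlap
    starts = list(range(0, n - block, step))
    starts.append(n - block)
    return tuple(starts)


def plan_blocks(
    shape: tuple[int, int, int],
    block: tuple[int, int, int] = (100, 100, 100),
    overlap_frac: float = 0.10,
) -> BlockLayout:
    """Tile a volume with overlapping blocks (default 100^3, 10% overlap).

    Blocks cover every voxel; the last block of each axis is shifted inward
    so it ends flush with the volume.
    """
    if not 0.0 <= overlap_frac < 0.5:
        raise ValueError("overlap fraction must be in [0, 0.5)")
    block = tuple(min(b, s) for b, s in zip(block, shape))
    overlap = tuple(int(round(overlap_frac * b)) for b in block)
    starts = tuple(
        _axis_starts(s, b, o) for s, b, o in zip(shape, block, overlap)
    )
    return BlockLayout(tuple(shape), block, overlap, starts)


def _tent(n: int, ramp: int, first: bool, last: bool) -> np.ndarray:
    """Trapezoidal blend profile along one axis; edge blocks get clamped ramps."""
    w = np.ones(n)
    if ramp > 0:
        r = (np.arange(ramp) + 1.0) / (ramp + 1.0)
        if not first:
            w[:ramp] = r
        if not last:
            w[-ramp:] = r[::-1]
    return w


class IncompleteLayoutError(ValueError):
    """Raised when stitched blocks do not match the planned layout."""


def stitch_blocks(
    blocks: list[SHField],
    origins: list[tuple[int, int, int]],
    layout: BlockLayout,
) -> SHField:
    """Fuse reconstructed blocks by normalized linear blending.

    All 15 channels are blended with the same weights; the per-voxel weight
    field is normalized to sum to exactly 1 (partition of unity).
    """
    expected = set(layout.blocks)
    got = set(map(tuple, origins))
    if got != expected:
        raise IncompleteLayoutError(
            f"layout expects {len(expected)} blocks at fixed origins; got {len(got)}"
        )
    out = np.zeros((N_CHANNELS,) + layout.shape)
    wsum = np.zeros(layout.shape)
    for fld, origin in zip(blocks, origins):
        if fld.shape != layout.block:
            raise IncompleteLayoutError(
                f"block at {origin} has shape {fld.shape}, expected {layout.block}"
            )
        sl = layout.slices(origin)
        w = np.ones(layout.block)
        for ax in range(3):
            first = origin[ax] == 0
            last = origin[ax] + layout.block[ax] == layout.shape[ax]
            prof = _tent(layout.block[ax], layout.overlap[ax], first, last)
            w *= prof.reshape([-1 if i == ax else 1 for i in range(3)])
        out[(slice(None),) + sl] += fld.coeffs * w
        wsum[sl] += w
    if np.any(wsum <= 0):
        raise IncompleteLayoutError("blocks do not cover the volume")
    out /= wsum
    return SHField(out, blocks[0].voxel_size)


def reconstruct_blockwise(
    measurements,
    layout: BlockLayout,
    reconstruct_block,
    halo: int = 0,
) -> SHField:
    """Reconstruct a volume block by block and stitch the results.

    ``measurements`` is a list of MeasurementSet (one per view);
    ``reconstruct_block(sub_measurements) -> SHField`` runs the chosen
    estimator on one cropped sub-volume.  ``halo`` adds a margin around each
    block during reconstruction (clipped at volume edges) that is trimmed
    before blending, keeping deconvolution edge effects out of the seams.
    """
    blocks, origins = [], []
    for origin in layout.blocks:
        lo = [max(o - halo, 0) for o in origin]
        hi = [
            min(o + b + halo, s)
            for o, b, s in zip(origin, layout.block, layout.shape)
        ]
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        subs = [
            type(m)(
                m.volumes[(slice(None),) + sl], m.meta, m.voxel_size
            )
            for m in measurements
        ]
        fld = reconstruct_block(subs)
        trim = tuple(
            slice(o - a, o - a + b) for o, a, b in zip(origin, lo, layout.block)
        )
        blocks.append(SHField(fld.coeffs[(slice(None),) + trim], fld.voxel_size))
        origins.append(origin)
    return stitch_blocks(blocks, origins, layout)
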