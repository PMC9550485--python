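"""Spatial-transformer warping of volumes and label maps.

``warp`` resamples a moving image at the displaced grid i' = i + u(i) with
trilinear interpolation over the 8 integer neighbours of i', weighting each
neighbour j by prod_d (1 - |j_d - i'_d|).  The same kernel backs the
differentiable layer used in training (:func:`mhnet.autodiff.grid_pull`);
here it is exposed on the plain :class:`~mhnet.volumes.Volume` types.

Label maps are resampled with nearest-neighbour lookup so label identities
are never blended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, grid_pull
from .volumes import DisplacementField, LabelMap, Volume

__all__ = ["WarpConfig", "warp", "warp_labels"]

_BOUNDARY_MODES = ("clamp", "zeros")


@dataclass
class WarpConfig:
    """Out-of-domain sampling policy: clamp to the border or read zeros."""

    boundary_mode: str = "clamp"

    def __post_init__(self):
        if self.boundary_mode not in _BOUNDARY_MODES:
            raise ValueError(
                f"boundary_mode must be one of {_BOUNDARY_MODES}, "
                f"got {self.boundary_mode!r}"
            )


def _check_shapes(vol_shape, phi: DisplacementField):
    if tuple(phi.shape) != tuple(vol_shape):
        raise ValueError(
            f"displacement field spatial shape {tuple(phi.shape)} does not "
            f"match volume shape {tuple(vol_shape)}"
        )


def warp(m: Volume, phi: DisplacementField, cfg: WarpConfig | None = None) -> Volume:
    """Trilinear warp of ``m`` by the voxel-unit displacement field ``phi``."""
    cfg = cfg or WarpConfig()
    _check_shapes(m.shape, phi)
    out = grid_pull(
        Tensor(m.data[None].astype(np.float64)),
        Tensor(phi.u.astype(np.float64)),
        mode=cfg.boundary_mode,
    )
    return Volume(out.data[0].astype(np.float32), m.spacing)


def warp_labels(
    l: LabelMap, phi: DisplacementField, cfg: WarpConfig | None = None
) -> LabelMap:
    """Nearest-neighbour warp of a label map (labels stay integral)."""
    cfg = cfg or WarpConfig()
    _check_shapes(l.shape, phi)
    X, Y, Z = l.shape
    grid = np.meshgrid(
        np.arange(X), np.arange(Y), np.arange(Z), indexing="ij"
    )
    idx = [np.rint(grid[d] + phi.u[d]).astype(np.intp) for d in range(3)]
    if cfg.boundary_mode == "clamp":
        for d, n in enumerate((X, Y, Z)):
            np.clip(idx[d], 0, n - 1, out=idx[d])
        out = l.labels[tuple(idx)]
    else:
        inside = np.ones((X, Y, Z), dtype=bool)
        for d, n in enumerate((X, Y, Z)):
            inside &= (idx[d] >= 0) & (idx[d] < n)
            np.clip(idx[d], 0, n - 1, out=idx[d])
        out = np.where(inside, l.labels[tuple(idx)], 0)
    return LabelMap(out)
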