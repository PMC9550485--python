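"""Training objective: local NCC similarity, diffusion smoothness, total.

The similarity term is the squared, locally windowed normalized
cross-correlation, averaged over voxels — the windowed form standard in
intensity-based registration, whose value lies in [0, 1] (1 when the warped
moving image is a local affine rescaling of the reference inside every
window).  It is used negated as the similarity loss.  The regularizer is
the diffusion penalty: the squared forward differences of all three
displacement components along all three axes, averaged over voxels.  The
total loss is ``alpha * L_sim + lam * L_smooth``; only the alpha:lam ratio
matters for the optimum, and both default to the settings that performed
best in the source study (alpha=1, lam=3).

Every function comes in two layers: a graph-level version on autodiff
tensors (used inside training) and a plain wrapper on Volume /
DisplacementField returning floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, _box_sum_nd, box_sum, grid_pull
from .volumes import DisplacementField, Volume
from .warp import WarpConfig, warp

__all__ = [
    "LossConfig",
    "ncc",
    "similarity_loss",
    "smoothness_loss",
    "total_loss",
    "ncc_graph",
    "smoothness_graph",
    "total_loss_graph",
]


@dataclass
class LossConfig:
    alpha: float = 1.0
    lam: float = 3.0
    ncc_window: int = 9
    eps: float = 1e-5

    def __post_init__(self):
        if self.alpha < 0 or self.lam < 0:
            raise ValueError("loss weights must be non-negative")
        if self.ncc_window < 1 or self.ncc_window % 2 != 1:
            raise ValueError("ncc_window must be an odd integer >= 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


# ---------------------------------------------------------------------------
# graph-level (differentiable) forms
# ---------------------------------------------------------------------------

def ncc_graph(f: Tensor, w: Tensor, cfg: LossConfig) -> Tensor:
    """Mean squared local NCC of two (X, Y, Z) tensors, in [0, 1].

    Window statistics are moving sums over a cube of edge
    ``cfg.ncc_window``, normalized by the number of in-bounds voxels in
    each window (so border windows are proper correlations over their
    truncated support).  The per-voxel squared correlation is
    cross^2 / (var_f * var_w + eps); windows with no variance contribute 0
    rather than dividing by zero.
    """
    win = cfg.ncc_window
    inv_n = Tensor(
        (1.0 / _box_sum_nd(np.ones(f.shape, dtype=np.float64), win)).astype(
            f.dtype
        )
    )
    sum_f = box_sum(f, win)
    sum_w = box_sum(w, win)
    sum_ff = box_sum(f * f, win)
    sum_ww = box_sum(w * w, win)
    sum_fw = box_sum(f * w, win)
    cross = sum_fw - sum_f * sum_w * inv_n
    var_f = sum_ff - sum_f * sum_f * inv_n
    var_w = sum_ww - sum_w * sum_w * inv_n
    cc = (cross * cross) / (var_f * var_w + cfg.eps)
    return cc.mean()


def smoothness_graph(u: Tensor) -> Tensor:
    """Diffusion penalty of a (3, X, Y, Z) displacement tensor.

    Sum over the 9 (component, axis) pairs of the mean squared forward
    difference; voxels without a forward neighbour along an axis are
    excluded from that axis's mean, so a unit-slope ramp scores exactly 1.
    """
    total = None
    for axis in range(1, 4):
        lead = tuple(
            slice(1, None) if a == axis else slice(None) for a in range(4)
        )
        lag = tuple(
            slice(None, -1) if a == axis else slice(None) for a in range(4)
        )
        d = u[lead] - u[lag]
        term = (d * d).mean() * 3.0  # mean over components folded in
        total = term if total is None else total + term
    return total


def total_loss_graph(
    f: Tensor, m: Tensor, u: Tensor, cfg: LossConfig, boundary_mode: str = "clamp"
) -> Tensor:
    """alpha * (-NCC(f, m∘phi)) + lam * smoothness(phi) on tensors."""
    warped = grid_pull(m.reshape(1, *m.shape), u, mode=boundary_mode)
    sim = -ncc_graph(f, warped.reshape(*f.shape), cfg)
    return sim * cfg.alpha + smoothness_graph(u) * cfg.lam


# ---------------------------------------------------------------------------
# Volume-facing wrappers
# ---------------------------------------------------------------------------

def _check_same_shape(f: Volume, w: Volume):
    if f.shape != w.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {w.shape}")


def ncc(f: Volume, w: Volume, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    _check_same_shape(f, w)
    return float(
        ncc_graph(
            Tensor(f.data.astype(np.float64)),
            Tensor(w.data.astype(np.float64)),
            cfg,
        ).item()
    )


def similarity_loss(
    f: Volume,
    m: Volume,
    phi: DisplacementField,
    cfg: LossConfig | None = None,
    warp_cfg: WarpConfig | None = None,
) -> float:
    """-NCC between the reference and the warped moving image; in [-1, 0]."""
    cfg = cfg or LossConfig()
    return -ncc(f, warp(m, phi, warp_cfg), cfg)


def smoothness_loss(phi: DisplacementField) -> float:
    return float(smoothness_graph(Tensor(phi.u.astype(np.float64))).item())


def total_loss(
    f: Volume,
    m: Volume,
    phi: DisplacementField,
    cfg: LossConfig | None = None,
    warp_cfg: WarpConfig | None = None,
) -> float:
    cfg = cfg or LossConfig()
    return cfg.alpha * similarity_loss(f, m, phi, cfg, warp_cfg) + cfg.lam * (
        smoothness_loss(phi)
    )
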