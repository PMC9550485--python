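"""Pairwise cross-registration dataset augmentation.

A training set of N volumes is expanded by registering every ordered pair
of distinct originals (reference X, moving Y) and keeping the warped
moving image Y' as a new sample: N(N-1) new images, N^2 in total after
merging with the originals.  The registration backend is pluggable:

``identity``
    phi = 0; the "new" image equals its moving image (testing only);
``iterative``
    a self-contained optimizer minimizing the training objective (NCC +
    diffusion) directly over a displacement field per pair — the default,
    with no external tooling required;
``model``
    a previously trained :class:`~mhnet.training.MHNetRegistration`;
``command``
    an external registration command template for users who have one
    installed (e.g. an ANTs quick-SyN invocation).
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .losses import LossConfig, total_loss_graph
from .training import Adam, MHNetRegistration
from .volumes import DisplacementField, Volume, read_volume, write_volume
from .warp import WarpConfig, warp

__all__ = [
    "AugmentationPlan",
    "plan_augmentation",
    "run_augmentation",
    "identity_backend",
    "IterativeBackend",
    "ModelBackend",
    "CommandBackend",
    "iterative_register",
]


@dataclass
class AugmentationPlan:
    originals: list
    tasks: list  # ordered (reference_id, moving_id) pairs

    def __post_init__(self):
        n = len(self.originals)
        if len(self.tasks) != n * (n - 1):
            raise ValueError("plan must contain exactly N(N-1) tasks")
        if any(r == m for r, m in self.tasks):
            raise ValueError("plan contains a self-pair")

    @property
    def n_new(self) -> int:
        return len(self.tasks)

    @property
    def n_total(self) -> int:
        """Training-set size after merging originals with new images."""
        return len(self.originals) + len(self.tasks)


def plan_augmentation(ids) -> AugmentationPlan:
    """All N(N-1) ordered pairs of distinct identifiers, in deterministic
    lexicographic-by-position order."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("augmentation identifiers must be distinct")
    if len(ids) < 1:
        raise ValueError("at least one identifier is required")
    tasks = [(r, m) for r in ids for m in ids if r != m]
    return AugmentationPlan(originals=ids, tasks=tasks)


def derived_id(reference_id, moving_id) -> str:
    return f"{moving_id}__to__{reference_id}"


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------

def identity_backend(reference: Volume, moving: Volume) -> Volume:
    """phi = 0: returns the moving image unchanged (contract testing)."""
    return Volume(moving.data.copy(), moving.spacing)


def iterative_register(
    reference: Volume,
    moving: Volume,
    loss: LossConfig | None = None,
    n_iters: int = 100,
    lr: float = 0.5,
    boundary_mode: str = "clamp",
) -> DisplacementField:
    """Gradient-based registration of one pair by direct field optimization.

    ADAM minimizes alpha*(-NCC) + lam*smoothness over a free (3, X, Y, Z)
    displacement initialized at zero.  Slower than a trained network but
    self-contained; used as the default augmentation backend.
    """
    if reference.shape != moving.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {moving.shape}")
    loss = loss or LossConfig()
    f = Tensor(reference.data.astype(np.float64))
    m = Tensor(moving.data.astype(np.float64))
    u = Tensor(np.zeros((3, *reference.shape)), requires_grad=True)
    opt = Adam([u], lr=lr)
    for _ in range(n_iters):
        value = total_loss_graph(f, m, u, loss, boundary_mode=boundary_mode)
        if not np.isfinite(value.item()):
            raise FloatingPointError("non-finite loss during iterative registration")
        opt.zero_grad()
        value.backward()
        opt.step()
    return DisplacementField(u.data.astype(np.float32))


@dataclass
class IterativeBackend:
    loss: LossConfig = field(default_factory=LossConfig)
    n_iters: int = 100
    lr: float = 0.5
    boundary_mode: str = "clamp"

    def __call__(self, reference: Volume, moving: Volume) -> Volume:
        phi = iterative_register(
            reference, moving, self.loss, self.n_iters, self.lr,
            self.boundary_mode,
        )
        return warp(moving, phi, WarpConfig(self.boundary_mode))


@dataclass
class ModelBackend:
    """Registers each pair with a trained network in one forward pass."""

    estimator: MHNetRegistration

    def __call__(self, reference: Volume, moving: Volume) -> Volume:
        return self.estimator.transform([(reference, moving)])[0]


@dataclass
class CommandBackend:
    """Shells out to an external registration tool.

    ``template`` is formatted with {reference}, {moving} and {output}
    NIfTI paths; the command must write the warped moving image to
    {output}.
    """

    template: str

    def __call__(self, reference: Volume, moving: Volume) -> Volume:
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            rp, mp, op = tmp / "ref.nii.gz", tmp / "mov.nii.gz", tmp / "out.nii.gz"
            write_volume(reference, rp)
            write_volume(moving, mp)
            cmd = self.template.format(reference=rp, moving=mp, output=op)
            subprocess.run(shlex.split(cmd), check=True)
            return read_volume(op)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def run_augmentation(plan: AugmentationPlan, volumes: dict, backend=None):
    """Execute every task of ``plan``.

    Returns (new_volumes, failures): a dict mapping derived identifiers to
    warped moving Volumes, and a list of (reference_id, moving_id, error)
    for tasks whose backend raised.  Execution continues past failures.
    """
    backend = backend or IterativeBackend()
    missing = [i for i in plan.originals if i not in volumes]
    if missing:
        raise KeyError(f"volumes missing for identifiers: {missing}")
    new, failures = {}, []
    for ref_id, mov_id in plan.tasks:
        out_id = derived_id(ref_id, mov_id)
        if out_id in volumes:
            raise ValueError(f"derived identifier collides with original: {out_id}")
        try:
            new[out_id] = backend(volumes[ref_id], volumes[mov_id])
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            failures.append((ref_id, mov_id, str(exc)))
    return new, failures
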