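"""Synthetic phantoms with known ground-truth deformations.

Generates desk-scale stand-ins for affinely pre-aligned brain volumes: a
smooth intensity phantom made of nested soft-edged ellipsoidal structures
(labelled 1..n from outermost to innermost, background 0), a smooth random
displacement field of controlled amplitude and correlation length, and
moving/reference pairs produced by warping the phantom with that field.
Everything is deterministic per seed, so registration quality and field
recovery are both measurable without any external data.

These phantoms emulate the geometry of labelled anatomy, not MRI physics:
there is no bias field, no modality contrast, and the deformations are
globally smooth Gaussian random fields rather than anatomical variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .volumes import DisplacementField, LabelMap, Volume
from .warp import WarpConfig, warp, warp_labels

__all__ = ["PhantomSpec", "make_phantom", "make_smooth_field", "make_pair"]


@dataclass
class PhantomSpec:
    shape: tuple = (32, 32, 32)
    n_structures: int = 6
    deform_amplitude: float = 3.0
    deform_smoothness: float = 8.0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be three dimensions of at least 4")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        if self.deform_smoothness <= 0:
            raise ValueError("deform_smoothness must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_phantom(spec: PhantomSpec):
    """Multi-structure ellipsoid phantom; returns (Volume, LabelMap).

    Label 1 is a large soft-edged ellipsoid filling most of the volume (the
    organ outline); labels 2..n_structures are small ellipsoidal blobs
    scattered inside it (stand-ins for compact anatomical structures, a few
    voxels across, so their Dice is sensitive to voxel-scale misalignment).
    Intensity is a per-structure level plus a smooth random texture that
    gives every neighbourhood local contrast for windowed NCC, softened by
    a small Gaussian blur.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = spec.shape
    coords = np.meshgrid(
        np.arange(X), np.arange(Y), np.arange(Z), indexing="ij"
    )
    shape_arr = np.array(spec.shape, dtype=float)
    labels = np.zeros(spec.shape, dtype=np.int32)
    intensity = np.zeros(spec.shape, dtype=np.float64)
    n = spec.n_structures

    def paint(centre, radii, label, level):
        dist = sum(((coords[d] - centre[d]) / radii[d]) ** 2 for d in range(3))
        mask = dist <= 1.0
        labels[mask] = label
        intensity[mask] = level

    outer_centre = shape_arr / 2.0 + rng.uniform(-1.0, 1.0, size=3)
    outer_radii = np.maximum(shape_arr * 0.42 * rng.uniform(0.92, 1.0, size=3), 2.0)
    paint(outer_centre, outer_radii, 1, 0.35)

    # compact inner structures, kept apart so each label survives
    min_dim = float(min(spec.shape))
    placed = []
    for i in range(2, n + 1):
        for _ in range(200):
            radii = rng.uniform(0.05, 0.11, size=3) * min_dim
            radii = np.maximum(radii, 1.6)
            centre = outer_centre + rng.uniform(-0.55, 0.55, size=3) * outer_radii
            if all(
                np.linalg.norm(centre - c) > r + max(radii) + 1.0
                for c, r in placed
            ):
                break
        paint(centre, radii, i, 0.45 + 0.55 * (i - 1) / max(n - 1, 1))
        placed.append((centre, max(radii)))

    texture = gaussian_filter(rng.normal(0.0, 1.0, spec.shape), 1.5)
    tex_sd = texture.std()
    if tex_sd > 0:
        texture *= 0.08 / tex_sd
    intensity = gaussian_filter(intensity, 0.8) + texture * (labels > 0)
    intensity = np.clip(intensity, 0.0, 1.0)
    return Volume(intensity.astype(np.float32)), LabelMap(labels)


def make_smooth_field(spec: PhantomSpec) -> DisplacementField:
    """Gaussian-smoothed random vector field, rescaled so the maximum
    displacement magnitude equals ``deform_amplitude`` (voxels).

    ``deform_smoothness`` is a FWHM-like correlation length in voxels; the
    Gaussian kernel sigma is half of it.  Smoothing is periodic, which
    keeps the field statistically stationary across the volume (no
    boundary attenuation of the deformation).
    """
    rng = np.random.default_rng(spec.seed + 1)
    if spec.deform_amplitude == 0:
        return DisplacementField(np.zeros((3, *spec.shape), dtype=np.float32))
    sigma = spec.deform_smoothness / 2.0
    u = rng.normal(0.0, 1.0, size=(3, *spec.shape))
    for d in range(3):
        u[d] = gaussian_filter(u[d], sigma, mode="wrap")
    mag = np.sqrt((u**2).sum(axis=0)).max()
    if mag > 0:
        u *= spec.deform_amplitude / mag
    return DisplacementField(u.astype(np.float32))


def make_pair(spec: PhantomSpec):
    """A registration test case with known ground truth.

    Returns (fixed, moving, fixed_labels, moving_labels, truth) where
    moving = warp(fixed, truth) + noise and the label maps are warped with
    nearest-neighbour sampling.  Registering moving onto fixed should
    approximately invert ``truth``.
    """
    fixed, fixed_labels = make_phantom(spec)
    truth = make_smooth_field(spec)
    cfg = WarpConfig("clamp")
    moving = warp(fixed, truth, cfg)
    moving_labels = warp_labels(fixed_labels, truth, cfg)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 2)
        noisy = moving.data + rng.normal(0.0, spec.noise_sd, spec.shape)
        moving = Volume(np.clip(noisy, 0.0, 1.0).astype(np.float32))
    return fixed, moving, fixed_labels, moving_labels, truth
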