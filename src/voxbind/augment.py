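"""Rigid-transform augmentation for contrastive views and training.

Augmentation acts on atomic coordinates, not on the voxel array: a random
proper rotation (uniform over SO(3) via the quaternion method) about the
ligand centroid plus a bounded uniform translation is applied before
voxelization.  Working in coordinate space permits arbitrary rotation
angles with no grid-interpolation artifacts; atoms pushed outside the box
simply deposit nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pocket import Pocket
from .voxelize import GridSpec, VoxelGrid, gaussian_blur, voxelize_atoms

__all__ = ["RigidTransform", "ViewPair", "sample_transform", "apply_transform",
           "make_view_pair"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation, y = R x + t."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), Angstrom

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class ViewPair:
    """Two independently augmented grids of the same pocket."""

    view_i: VoxelGrid
    view_j: VoxelGrid
    source_id: str = ""

    def __post_init__(self):
        if self.view_i.shape != self.view_j.shape:
            raise ValueError("view grids must share a shape")


def _quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def sample_transform(rng_seed: int, max_shift: float = 2.0) -> RigidTransform:
    """Draw a uniform random rotation and a bounded uniform translation.

    The rotation comes from a normalized 4-vector of iid standard normals
    (uniform quaternion on S3, hence uniform over SO(3)); the translation is
    uniform on the cube [-max_shift, +max_shift]^3.  Deterministic given the
    seed.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    rng = np.random.default_rng(rng_seed)
    q = rng.standard_normal(4)
    R = _quaternion_to_matrix(q)
    t = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(rotation=R, translation=t)


def apply_transform(p: Pocket, tf: RigidTransform) -> Pocket:
    """Apply a rigid transform to every atom (about the current origin)."""
    def move(atoms):
        return [replace(a, coords=tf.apply(a.coords)) for a in atoms]

    return Pocket(
        rna_atoms=move(p.rna_atoms),
        ligand_atoms=move(p.ligand_atoms),
        radius=p.radius,
        center=p.center,
        centered=p.centered,
        source_id=p.source_id,
    )


def augmented_grid(
    p: Pocket, spec: GridSpec, seed: int, max_shift: float = 2.0
) -> VoxelGrid:
    """One augmented, blurred grid of a centred pocket."""
    if not p.centered:
        raise ValueError("pocket must be centered before augmentation")
    tf = sample_transform(seed, max_shift=max_shift)
    return gaussian_blur(voxelize_atoms(apply_transform(p, tf), spec))


def make_view_pair(
    p: Pocket,
    spec: GridSpec,
    seed_i: int,
    seed_j: int,
    max_shift: float = 2.0,
) -> ViewPair:
    """Two independently transformed grids of one pocket (the Si/Sj pair)."""
    return ViewPair(
        view_i=augmented_grid(p, spec, seed_i, max_shift),
        view_j=augmented_grid(p, spec, seed_j, max_shift),
        source_id=p.source_id,
    )
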