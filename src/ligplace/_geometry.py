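"""Rigid-body geometry helpers: rotations, Kabsch superposition, transforms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InputError


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (coordinates in Å)."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def rotation_from_vector(rvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (axis * angle, radians)."""
    return Rotation.from_rotvec(np.asarray(rvec, dtype=float)).as_matrix()


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Haar measure) from a seeded generator."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares optimal superposition of `mobile` onto `target`.

    Classic Kabsch/McLachlan solution via SVD of the covariance matrix;
    both inputs are (n, 3) arrays with row-wise correspondence, n >= 3.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("paired (n, 3) coordinate arrays required")
    if len(mobile) < 3:
        raise InputError(f"need >= 3 paired atoms for superposition, got {len(mobile)}")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rotation=rot, translation=ct - rot @ cm)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two (n, 3) arrays in correspondence."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, eigenvalues (descending) and right-handed axis matrix.

    Axes are the eigenvectors of the (unweighted) gyration tensor, returned
    as columns of a rotation matrix with det = +1.
    """
    coords = np.asarray(coords, dtype=float)
    c = coords.mean(axis=0)
    x = coords - c
    gyr = x.T @ x / max(len(x), 1)
    evals, evecs = np.linalg.eigh(gyr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    return c, evals, evecs


def canonical_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and a rotation into a molecule-fixed canonical frame.

    Principal axes with signs fixed by the third moment along each axis, so
    the frame co-rotates with the coordinates: numerical surface integrals
    evaluated in this frame are invariant under global rigid motion.
    """
    c, _, axes = principal_axes(coords)
    x = coords - c
    for k in (0, 1):
        skew = float(np.sum((x @ axes[:, k]) ** 3))
        if skew < 0:
            axes[:, k] = -axes[:, k]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return c, axes


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit sphere points (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
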