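"""Rigid-body superposition and RMSD primitives.

Every scoring stage in the package (I-RMSD, L-RMSD, CDR loop RMSD,
TM-score search) reduces to two operations: an optimal rigid-body
superposition of paired coordinate sets (Kabsch algorithm) and a plain
root-mean-square deviation over a fixed correspondence.  All coordinates
are in Angstroms, double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "kabsch_superpose", "rmsd", "apply_transform"]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation followed by a translation: x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(rot) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation determinant must be +1 (proper rotation)")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation matrix must be orthonormal")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, vec) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(vec, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -(self.rotation.T @ self.translation))


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation over a fixed 1:1 correspondence.

    No superposition is performed.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise ValueError("expected non-empty (n, 3) coordinate arrays")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _check_not_collinear(centered: np.ndarray, label: str) -> None:
    # Exactly collinear (or coincident) points leave the rotation about the
    # common axis undetermined.
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-12 * max(1.0, sv[0]):
        raise ValueError(f"{label} coordinates are collinear; superposition is not unique")


def kabsch_superpose(coords_mobile, coords_target) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of `coords_mobile` onto `coords_target`.

    Returns the optimal proper-rotation transform and the RMSD after
    applying it.  The reflection case (determinant < 0) is corrected by
    negating the smallest-singular-value axis, so the result is always a
    rotation, never a mirror image.
    """
    mob = np.asarray(coords_mobile, dtype=float)
    tgt = np.asarray(coords_target, dtype=float)
    if mob.shape != tgt.shape:
        raise ValueError(f"coordinate sets differ in shape: {mob.shape} vs {tgt.shape}")
    if mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinate arrays")
    if mob.shape[0] < 3:
        raise ValueError("at least 3 point pairs are required for superposition")

    mob_c = mob - mob.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    _check_not_collinear(mob_c, "mobile")
    _check_not_collinear(tgt_c, "target")

    cov = mob_c.T @ tgt_c
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    tr = tgt.mean(axis=0) - rot @ mob.mean(axis=0)
    transform = RigidTransform(rot, tr)
    return transform, rmsd(transform.apply(mob), tgt)


def apply_transform(obj, transform: RigidTransform):
    """Apply a rigid transform to a coordinate array or a StructureModel.

    Returns a transformed copy; the input is not modified.
    """
    from .structure_model import StructureModel  # local import avoids a cycle

    if isinstance(obj, StructureModel):
        new = obj.copy()
        for residues in new.chains.values():
            for res in residues:
                for atom in res.atoms:
                    atom.position = transform.apply(atom.position)
        return new
    return transform.apply(np.asarray(obj, dtype=float))
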