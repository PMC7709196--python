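"""Unit-cell geometry and space-group symmetry primitives.

Coordinates are kept fractional throughout the package; the :class:`UnitCell`
owns the orthogonalization/fractionalization matrices used whenever distances
in angstroms are required (kernel radii, shift magnitudes, r.m.s.d.).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = ["UnitCell", "SymmetryOps"]


@dataclasses.dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell with cached coordinate-transform matrices.

    Parameters are the six standard cell constants: edge lengths ``a, b, c``
    in angstroms and angles ``alpha, beta, gamma`` in degrees.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edge lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def _cosines(self) -> tuple[float, float, float]:
        return tuple(math.cos(math.radians(x)) for x in self.angles)

    @property
    def volume(self) -> float:
        ca, cb, cg = self._cosines()
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(arg, 0.0))

    @property
    def orth_matrix(self) -> np.ndarray:
        """3x3 matrix taking fractional to orthogonal (Å) coordinates.

        Standard PDB convention: ``a`` along x, ``b`` in the xy plane.
        """
        ca, cb, cg = self._cosines()
        sg = math.sin(math.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def frac_matrix(self) -> np.ndarray:
        """Inverse of :attr:`orth_matrix`."""
        return np.linalg.inv(self.orth_matrix)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> orthogonal Å. Accepts (3,) or (n, 3) arrays."""
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        """Orthogonal Å -> fractional. Accepts (3,) or (n, 3) arrays."""
        return np.asarray(orth, dtype=float) @ self.frac_matrix.T

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal-space metric tensor G* = (Aᵀ A)⁻¹ with A = orth matrix."""
        a = self.orth_matrix
        return np.linalg.inv(a.T @ a)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of Miller indices; (3,) or (n, 3) input."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", h, self.reciprocal_metric, h)
        d = 1.0 / np.sqrt(inv_d2)
        return d[0] if np.asarray(hkl).ndim == 1 else d

    def min_image_distance(self, frac_a: np.ndarray, frac_b: np.ndarray) -> np.ndarray:
        """Orthogonal distance (Å) between fractional points, shortest periodic image.

        Searches the 27 neighbouring cells, which is exact for displacements
        shorter than half the shortest cell height (always the case for the
        matched-atom distances this package computes).
        """
        d = np.atleast_2d(np.asarray(frac_a, dtype=float) - np.asarray(frac_b, dtype=float))
        d -= np.round(d)
        shifts = np.array(
            [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
            dtype=float,
        )
        cand = d[:, None, :] + shifts[None, :, :]
        dist = np.linalg.norm(cand @ self.orth_matrix.T, axis=2).min(axis=1)
        return dist[0] if np.asarray(frac_a).ndim == 1 else dist

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


class SymmetryOps:
    """Space-group symmetry operators in fractional space.

    Stores (rotation, translation) pairs; rotations are integer matrices for
    crystallographic settings. Only used to expand models to P1 and to detect
    centric reflections — all map algebra in this package runs in P1.
    """

    def __init__(
        self,
        ops: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
        name: str = "P 1",
    ):
        if ops is None:
            ops = [(np.eye(3, dtype=int), np.zeros(3))]
        self.ops = [(np.asarray(r, dtype=int), np.asarray(t, dtype=float)) for r, t in ops]
        self.name = name
        if not any(np.array_equal(r, np.eye(3, dtype=int)) and np.allclose(t % 1.0, 0.0)
                   for r, t in self.ops):
            raise ValueError("symmetry operator set must contain the identity")

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self) -> Iterable[tuple[np.ndarray, np.ndarray]]:
        return iter(self.ops)

    @classmethod
    def p1(cls) -> "SymmetryOps":
        return cls()

    @classmethod
    def from_spacegroup(cls, name: str) -> "SymmetryOps":
        sg = gemmi.SpaceGroup(name)
        ops = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / 24.0
            tran = np.array(op.tran, dtype=float) / 24.0
            ops.append((rot.astype(int), tran))
        return cls(ops, name=sg.hm)

    @property
    def is_p1(self) -> bool:
        return len(self.ops) == 1

    def is_centric(self, hkl: np.ndarray) -> np.ndarray:
        """Boolean mask: reflection h is centric if h·R = -h for some operator R."""
        h = np.atleast_2d(np.asarray(hkl, dtype=int))
        mask = np.zeros(len(h), dtype=bool)
        for rot, _ in self.ops:
            mask |= np.all(h @ rot == -h, axis=1)
        out = mask
        return out[0] if np.asarray(hkl).ndim == 1 else out

    def apply(self, frac: np.ndarray) -> list[np.ndarray]:
        """All symmetry images of fractional coordinates (n, 3), wrapped to [0, 1)."""
        x = np.atleast_2d(np.asarray(frac, dtype=float))
        return [(x @ np.asarray(rot, dtype=float).T + tran) % 1.0 for rot, tran in self.ops]
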