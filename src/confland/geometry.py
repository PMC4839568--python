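"""Optimal rigid-body superposition and all-pairs RMSD matrices.

The dissimilarity between two conformations is the root-mean-square
deviation of their core atoms after least-squares superposition (Kabsch).
Only proper rotations are allowed, so mirror images are never matched.
The fit set equals the measure set and no mass weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import CoordinateSet

__all__ = [
    "DissimilarityMatrix",
    "optimal_superposition",
    "pairwise_rmsd_matrix",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric all-pairs RMSD matrix with structure labels (Angstrom)."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError(f"D shape {self.D.shape} does not match {n} labels")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("non-finite dissimilarities")
        if np.any(self.D < 0):
            raise ValueError("negative dissimilarities")
        if not np.allclose(self.D, self.D.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-8):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        # exact symmetry for downstream eigendecompositions
        self.D = 0.5 * (self.D + self.D.T)
        np.fill_diagonal(self.D, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_csv(self, path: str | Path) -> None:
        """Write as delimited text with a header row of labels."""
        pd.DataFrame(self.D, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.columns.astype(str)), D=df.to_numpy(float))

    def to_npz(self, path: str | Path) -> None:
        """Binary container: arrays ``labels`` and ``D``."""
        np.savez(path, labels=np.asarray(self.labels), D=self.D)

    @classmethod
    def from_npz(cls, path: str | Path) -> "DissimilarityMatrix":
        with np.load(path, allow_pickle=False) as data:
            return cls(labels=[str(x) for x in data["labels"]], D=data["D"])


def _as_coords(obj) -> np.ndarray:
    return obj.coords if isinstance(obj, CoordinateSet) else np.asarray(obj, float)


def _check_compatible(A: CoordinateSet, B: CoordinateSet) -> None:
    if A.atom_index != B.atom_index:
        mism = next(
            (
                (a, b)
                for a, b in zip(A.atom_index, B.atom_index)
                if a != b
            ),
            None,
        )
        detail = f"; first mismatch {mism[0]} vs {mism[1]}" if mism else ""
        raise ValueError(
            f"atom sets of {A.label!r} and {B.label!r} differ{detail}"
        )


def optimal_superposition(
    A: CoordinateSet | np.ndarray, B: CoordinateSet | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of ``A`` onto ``B``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1) and
    ``t`` a translation such that ``A @ R.T + t`` minimizes the RMSD to
    ``B``.  Degenerate inputs (all atoms coincident) return the identity
    rotation.
    """
    if isinstance(A, CoordinateSet) and isinstance(B, CoordinateSet):
        _check_compatible(A, B)
    a = _as_coords(A)
    b = _as_coords(B)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    m = a.shape[0]
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    if np.allclose(a0, 0.0) or np.allclose(b0, 0.0):
        R = np.eye(3)
    else:
        rot, _ = Rotation.align_vectors(b0, a0)
        R = rot.as_matrix()
    t = cb - R @ ca
    diff = a0 @ R.T - b0
    rmsd = float(np.sqrt((diff * diff).sum() / m))
    return R, t, rmsd


def rmsd_after_superposition(
    A: CoordinateSet | np.ndarray, B: CoordinateSet | np.ndarray
) -> float:
    """RMSD of ``A`` vs ``B`` after optimal superposition (Angstrom)."""
    return optimal_superposition(A, B)[2]


def pairwise_rmsd_matrix(sets: Sequence[CoordinateSet]) -> DissimilarityMatrix:
    """All-pairs superposed RMSD over a shared atom index.

    Each unordered pair is computed once; the diagonal is zero.
    """
    if len(sets) == 0:
        raise ValueError("need at least one coordinate set")
    first = sets[0]
    for other in sets[1:]:
        _check_compatible(first, other)
    n = len(sets)
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rmsd_after_superposition(sets[i], sets[j])
    return DissimilarityMatrix(labels=[s.label for s in sets], D=D)
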