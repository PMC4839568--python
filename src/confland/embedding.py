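"""Classical multidimensional scaling and out-of-sample projection.

Classical MDS (cMDS) converts a squared-dissimilarity matrix into a
centered Gram matrix by double centering,

    B = -1/2 J D^2 J,      J = I - 1 w^T / sum(w),

and factorizes B by eigendecomposition, ranking axes by eigenvalue.  For a
non-Euclidean dissimilarity such as superposed RMSD, B may have negative
eigenvalues; it is then replaced by the nearest (Frobenius-norm) symmetric
positive-semidefinite matrix before factorization.  Component k of the
embedding is the k-th eigenvector scaled so its squared norm equals the
eigenvalue, and the fraction of variance it explains is lambda_k divided
by the sum of positive eigenvalues.

A new sample with distance vector ``a`` to the n training objects is
projected *without refitting*: the bordered squared-distance matrix is
double-centered with zero weight on the new point, which yields a border
vector ``b`` and scalar ``beta``, and the projected coordinates are the
least-squares solution

    y = (X^T X)^{-1} X^T b,

obtained by dropping the quadratic ``(beta - y^T y)^2`` term of the exact
out-of-sample objective.  The cost per sample is linear in n and
independent of any previously projected samples, which is what makes the
method usable on microsecond-scale trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import DissimilarityMatrix, rmsd_after_superposition
from .structure_io import CoordinateSet

__all__ = [
    "EmbeddingModel",
    "OOSProjection",
    "double_center",
    "nearest_psd",
    "fit_cmds",
    "project_out_of_sample",
    "project_trajectory",
]

#: Eigenvalues below this fraction of the largest are treated as zero.
ZERO_EIGENVALUE_RTOL = 1e-9


def double_center(
    D: DissimilarityMatrix | np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted double centering of a squared-dissimilarity matrix.

    Computes ``B = -1/2 J S J^T`` where ``S`` is the element-wise square of
    the dissimilarities and ``J = I - 1 w^T / sum(w)`` is the weighted
    centering projector.  With uniform weights every row and column of the
    result sums to zero.
    """
    Dmat = D.D if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    n = Dmat.shape[0]
    if Dmat.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"weights shape {w.shape} does not match n={n}")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and not all zero")
        w = w / w.sum()
    S = Dmat**2
    J = np.eye(n) - np.outer(np.ones(n), w)
    B = -0.5 * (J @ S @ J.T)
    return 0.5 * (B + B.T)  # enforce exact symmetry


def nearest_psd(B: np.ndarray) -> np.ndarray:
    """Nearest symmetric positive-semidefinite matrix in Frobenius norm.

    Reconstructs ``B`` in its eigenvector basis with negative eigenvalues
    clipped to zero.  The Frobenius distance of the correction equals the
    root of the sum of squared clipped eigenvalues.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(B, B.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    evals, evecs = np.linalg.eigh(0.5 * (B + B.T))
    if np.all(evals >= 0):
        return B
    clipped = np.clip(evals, 0.0, None)
    Bp = (evecs * clipped) @ evecs.T
    return 0.5 * (Bp + Bp.T)


def _fix_signs(X: np.ndarray) -> np.ndarray:
    # reproducibility convention: largest-magnitude loading positive
    for k in range(X.shape[1]):
        col = X[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            X[:, k] = -col
    return X


@dataclass
class EmbeddingModel:
    """A fitted conformational landscape.

    Attributes
    ----------
    labels
        Training structure ids, in matrix order.
    X
        ``n x p`` component coordinates; column k has squared norm equal to
        ``eigenvalues[k]``.
    eigenvalues
        Retained eigenvalues, descending.
    all_eigenvalues
        Full spectrum of the centered Gram matrix (before the PSD
        correction), descending; used for variance accounting.
    weights
        The n centering masses (normalized).
    psd_adjusted / psd_correction
        Whether negative eigenvalues were clipped, and the Frobenius
        distance of that correction.
    strain
        Squared Frobenius residual between the centered Gram matrix and
        the inner products of the embedded coordinates.
    d2_row_means / d2_grand_mean
        Weighted means of the squared training dissimilarities, cached so
        out-of-sample projection is linear in n.
    training_coords
        Optional ``n x m x 3`` array of the training coordinate sets, kept
        so trajectory frames can be projected from raw coordinates.
    """

    labels: list[str]
    X: np.ndarray
    eigenvalues: np.ndarray
    all_eigenvalues: np.ndarray
    weights: np.ndarray
    psd_adjusted: bool
    psd_correction: float
    strain: float
    d2_row_means: np.ndarray
    d2_grand_mean: float
    selection_name: str = ""
    atom_index: tuple[tuple[int, str], ...] = ()
    training_coords: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def explained_variance(self) -> np.ndarray:
        """Per-retained-component fraction of positive-eigenvalue variance."""
        pos = self.all_eigenvalues[self.all_eigenvalues > 0].sum()
        if pos <= 0:
            return np.zeros(self.p)
        return np.clip(self.eigenvalues, 0.0, None) / pos

    def training_sets(self) -> list[CoordinateSet]:
        if self.training_coords is None:
            raise ValueError("model was saved without training coordinates")
        return [
            CoordinateSet(label, coords, self.atom_index)
            for label, coords in zip(self.labels, self.training_coords)
        ]

    def save(self, path: str | Path) -> None:
        """Serialize to an ``.npz`` container (documented binary format)."""
        arrays = dict(
            labels=np.asarray(self.labels),
            X=self.X,
            eigenvalues=self.eigenvalues,
            all_eigenvalues=self.all_eigenvalues,
            weights=self.weights,
            psd_adjusted=np.asarray(self.psd_adjusted),
            psd_correction=np.asarray(self.psd_correction),
            strain=np.asarray(self.strain),
            d2_row_means=self.d2_row_means,
            d2_grand_mean=np.asarray(self.d2_grand_mean),
            selection_name=np.asarray(self.selection_name),
            atom_resnums=np.asarray([n for n, _ in self.atom_index], dtype=int),
            atom_names=np.asarray([a for _, a in self.atom_index]),
        )
        if self.training_coords is not None:
            arrays["training_coords"] = self.training_coords
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with np.load(path, allow_pickle=False) as data:
            atom_index = tuple(
                (int(n), str(a))
                for n, a in zip(data["atom_resnums"], data["atom_names"])
            )
            return cls(
                labels=[str(x) for x in data["labels"]],
                X=data["X"],
                eigenvalues=data["eigenvalues"],
                all_eigenvalues=data["all_eigenvalues"],
                weights=data["weights"],
                psd_adjusted=bool(data["psd_adjusted"]),
                psd_correction=float(data["psd_correction"]),
                strain=float(data["strain"]),
                d2_row_means=data["d2_row_means"],
                d2_grand_mean=float(data["d2_grand_mean"]),
                selection_name=str(data["selection_name"]),
                atom_index=atom_index,
                training_coords=(
                    data["training_coords"] if "training_coords" in data else None
                ),
            )


@dataclass
class OOSProjection:
    """Out-of-sample projection of one query.

    ``a`` is the query's distance vector to the training structures, ``b``
    the border vector produced by zero-weight double centering, and
    ``beta_self`` the query's own centered self inner product — a
    diagnostic for how far the query lies outside the training span.
    """

    a: np.ndarray
    b: np.ndarray
    beta_self: float
    y: np.ndarray


def fit_cmds(
    D: DissimilarityMatrix,
    p: int = 2,
    weights: np.ndarray | None = None,
) -> EmbeddingModel:
    """Fit a classical-MDS embedding of a dissimilarity matrix.

    Parameters
    ----------
    D
        Symmetric dissimilarity matrix (e.g. all-pairs superposed RMSD).
    p
        Number of retained components (default 2; the first two components
        typically carry the bulk of a kinase ensemble's variance).  If p
        exceeds the number of positive eigenvalues it is truncated with a
        warning.
    weights
        Optional non-negative centering masses, one per structure.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    n = D.n
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    B = double_center(D, w)
    all_evals = np.sort(np.linalg.eigvalsh(B))[::-1]

    Bp = nearest_psd(B)
    psd_correction = float(np.linalg.norm(B - Bp))
    psd_adjusted = psd_correction > 0

    evals, evecs = np.linalg.eigh(Bp)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    tol = ZERO_EIGENVALUE_RTOL * max(evals[0], 0.0) if n else 0.0
    n_pos = int(np.sum(evals > tol))
    if n_pos == 0:
        # fully degenerate input (all structures identical)
        p_eff = p
        X = np.zeros((n, p))
        retained = np.zeros(p)
    else:
        p_eff = min(p, n_pos)
        if p_eff < p:
            warnings.warn(
                f"requested {p} components but only {n_pos} positive "
                f"eigenvalues; truncating to {n_pos}",
                stacklevel=2,
            )
        retained = evals[:p_eff]
        X = _fix_signs(evecs[:, :p_eff] * np.sqrt(retained))

    strain = float(np.linalg.norm(B - X @ X.T) ** 2)

    S = D.D**2
    row_means = S @ w
    grand_mean = float(w @ S @ w)

    return EmbeddingModel(
        labels=list(D.labels),
        X=X,
        eigenvalues=np.asarray(retained, float),
        all_eigenvalues=all_evals,
        weights=w,
        psd_adjusted=psd_adjusted,
        psd_correction=psd_correction,
        strain=strain,
        d2_row_means=row_means,
        d2_grand_mean=grand_mean,
    )


def project_out_of_sample(
    model: EmbeddingModel, a: np.ndarray
) -> OOSProjection:
    """Project one query into the fixed landscape from its distances.

    ``a`` holds the query's dissimilarities to the n training structures.
    The border vector is computed in O(n) from the cached training means —
    equivalent to double-centering the bordered matrix with zero weight on
    the query:

        b_i = -1/2 (a_i^2 - rowmean_i - wmean(a^2) + grandmean)
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (model.n,):
        raise ValueError(f"distance vector has shape {a.shape}, expected ({model.n},)")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("distances must be finite and non-negative")
    if model.X.size == 0 or np.allclose(model.X, 0.0):
        raise np.linalg.LinAlgError("zero-variance model: X^T X is singular")

    a2 = a**2
    w = model.weights
    wmean_a2 = float(w @ a2)
    b = -0.5 * (a2 - model.d2_row_means - wmean_a2 + model.d2_grand_mean)
    beta = wmean_a2 - 0.5 * model.d2_grand_mean
    y, *_ = np.linalg.lstsq(model.X, b, rcond=None)
    return OOSProjection(a=a, b=b, beta_self=float(beta), y=y)


def project_trajectory(
    model: EmbeddingModel,
    frames: Sequence[CoordinateSet],
    training_sets: Sequence[CoordinateSet] | None = None,
) -> np.ndarray:
    """Project trajectory frames into the landscape.

    For each frame the distance vector ``a`` is the superposed RMSD to all
    n training coordinate sets, and the frame is projected independently
    of every other frame (embarrassingly parallel contract).  Returns an
    ``n_frames x p`` array.
    """
    refs = list(training_sets) if training_sets is not None else model.training_sets()
    if len(refs) != model.n:
        raise ValueError("training set count does not match model")
    out = np.empty((len(frames), model.p), dtype=float)
    for i, frame in enumerate(frames):
        a = np.array([rmsd_after_superposition(frame, ref) for ref in refs])
        out[i] = project_out_of_sample(model, a).y
    return out
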