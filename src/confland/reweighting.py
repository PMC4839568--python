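"""Accelerated-MD boost parameters, exponential reweighting, free energy.

Accelerated MD ("dual boost") adds a non-negative boost potential dV(r) to
the dihedral and total potential energies whenever they fall below
thresholds E_dihed / E_total, flattening barriers.  The unbiased
probability of histogram bin i is recovered by exponential averaging: the
biased bin probability is multiplied by the bin average of exp(dV/kT) and
the product is renormalized,

    P_i = Pb_i <exp(dV/kT)>_i / sum_j Pb_j <exp(dV/kT)>_j.

The free-energy surface is F_i = -kT ln P_i, shifted so the occupied-bin
minimum is zero, with empty bins and energies at or above a display cap
(default 30 kcal/mol) reported at the cap.

Numerical note: the per-bin exponential average is evaluated in log space
(per-bin max subtracted before exponentiation), so arbitrarily large boost
energies cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KT_300K",
    "AmdParameters",
    "BoostedSample",
    "FreeEnergySurface",
    "amd_parameters",
    "default_edges",
    "reweight_histogram",
    "free_energy",
]

#: kB*T at 300 K in kcal/mol (the usual aMD simulation temperature).
KT_300K = 0.5961

#: Display cap for free energies, kcal/mol above the global minimum.
DEFAULT_CAP = 30.0


@dataclass(frozen=True)
class AmdParameters:
    """Dual-boost input parameters, kcal/mol."""

    E_dihed: float
    alpha_dihed: float
    E_total: float
    alpha_total: float


def amd_parameters(
    V_dihed_avg: float, V_total_avg: float, n_atoms: int
) -> AmdParameters:
    """Dual-boost thresholds from plain-MD average energies.

    E_dihed = V_dihed_avg + 0.3*V_dihed_avg, alpha_dihed = 0.3*V_dihed_avg/5;
    E_total = V_total_avg + 0.2*N_atoms, alpha_total = 0.2*N_atoms.
    """
    if n_atoms <= 0:
        raise ValueError("n_atoms must be positive")
    return AmdParameters(
        E_dihed=V_dihed_avg + 0.3 * V_dihed_avg,
        alpha_dihed=0.3 * V_dihed_avg / 5.0,
        E_total=V_total_avg + 0.2 * n_atoms,
        alpha_total=0.2 * n_atoms,
    )


@dataclass(frozen=True)
class BoostedSample:
    """One trajectory sample: frame index, collective variables, boost."""

    frame: int
    cv: tuple[float, ...]
    deltaV: float  # kcal/mol, >= 0


@dataclass
class FreeEnergySurface:
    """Histogram-based reweighted probability and free-energy grid.

    ``edges`` holds the bin edges per axis; ``Pb``/``P`` are the biased and
    unbiased probabilities per bin (empty bins have P = 0); ``F`` is the
    capped, min-shifted free energy in kcal/mol (filled by
    :func:`free_energy`); ``M`` is the total bin count.
    """

    edges: tuple[np.ndarray, ...]
    Pb: np.ndarray
    P: np.ndarray
    kT: float
    F: np.ndarray | None = None
    cap: float = DEFAULT_CAP

    @property
    def M(self) -> int:
        return int(self.P.size)

    @property
    def occupied(self) -> np.ndarray:
        return self.P > 0

    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per bin with centers, P and F."""
        grids = np.meshgrid(*self.centers(), indexing="ij")
        data = {f"cv{i + 1}": g.ravel() for i, g in enumerate(grids)}
        data["Pb"] = self.Pb.ravel()
        data["P"] = self.P.ravel()
        if self.F is not None:
            data["F_kcal_mol"] = self.F.ravel()
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _split_samples(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        cv, dv = samples
        cv = np.asarray(cv, dtype=float)
        dv = np.asarray(dv, dtype=float)
    else:
        seq: Sequence[BoostedSample] = list(samples)
        cv = np.asarray([s.cv for s in seq], dtype=float)
        dv = np.asarray([s.deltaV for s in seq], dtype=float)
    if cv.ndim == 1:
        cv = cv[:, None]
    if np.any(dv < 0):
        raise ValueError("boost energies must be non-negative")
    return cv, dv


def default_edges(
    cv: np.ndarray, bins: int | Sequence[int] = 100, pad: float = 0.02
) -> tuple[np.ndarray, ...]:
    """Bin edges spanning the sample range padded by ``pad`` per side."""
    cv = np.asarray(cv, dtype=float)
    if cv.ndim == 1:
        cv = cv[:, None]
    d = cv.shape[1]
    if np.isscalar(bins):
        bins = [int(bins)] * d
    edges = []
    for axis, nb in zip(range(d), bins):
        lo, hi = cv[:, axis].min(), cv[:, axis].max()
        span = hi - lo if hi > lo else max(abs(hi), 1.0)
        edges.append(np.linspace(lo - pad * span, hi + pad * span, nb + 1))
    return tuple(edges)


def reweight_histogram(
    samples,
    edges: Sequence[np.ndarray],
    kT: float = KT_300K,
    printed_normalization: bool = False,
) -> FreeEnergySurface:
    """Unbias a boosted sample histogram by per-bin exponential averaging.

    Parameters
    ----------
    samples
        Either a list of :class:`BoostedSample` or a ``(cv, deltaV)`` pair
        of arrays (``cv`` of shape ``(n,)`` or ``(n, d)``).
    edges
        Bin edges per collective-variable axis.
    kT
        Thermal energy in kcal/mol (default 300 K).
    printed_normalization
        Use the alternative normalization that divides by the plain sum of
        per-bin exponential averages instead of their biased-probability
        weighted sum.  That variant does not yield a normalized
        distribution in general and exists only for comparison.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    cv, dv = _split_samples(samples)
    edges = tuple(np.asarray(e, dtype=float) for e in edges)
    if cv.shape[1] != len(edges):
        raise ValueError(f"cv has {cv.shape[1]} axes but {len(edges)} edge sets given")

    shape = tuple(len(e) - 1 for e in edges)
    flat_idx, in_grid = _bin_indices(cv, edges, shape)
    if not np.any(in_grid):
        raise ValueError("no samples fall inside the histogram grid")
    idx = flat_idx[in_grid]
    dv_in = dv[in_grid]

    M = int(np.prod(shape))
    counts = np.bincount(idx, minlength=M).astype(float)
    occupied = counts > 0
    Pb = counts / counts.sum()

    # log of per-bin <exp(dV/kT)>, computed with per-bin max subtraction
    x = dv_in / kT
    bin_max = np.full(M, -np.inf)
    np.maximum.at(bin_max, idx, x)
    shifted_sum = np.zeros(M)
    np.add.at(shifted_sum, idx, np.exp(x - bin_max[idx]))
    log_avg = np.where(
        occupied, bin_max + np.log(shifted_sum, where=occupied, out=np.ones(M)) - np.log(counts, where=occupied, out=np.ones(M)), -np.inf
    )

    log_w = np.where(occupied, np.log(Pb, where=occupied, out=np.ones(M)) + log_avg, -np.inf)
    if printed_normalization:
        log_norm = _logsumexp(log_avg[occupied])
        P = np.where(occupied, np.exp(log_w - log_norm), 0.0)
    else:
        log_norm = _logsumexp(log_w[occupied])
        P = np.where(occupied, np.exp(log_w - log_norm), 0.0)

    return FreeEnergySurface(
        edges=edges,
        Pb=Pb.reshape(shape),
        P=P.reshape(shape),
        kT=float(kT),
    )


def _bin_indices(
    cv: np.ndarray, edges: tuple[np.ndarray, ...], shape: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Flat bin index per sample plus an in-grid mask (right edge inclusive)."""
    n = cv.shape[0]
    in_grid = np.ones(n, dtype=bool)
    multi = []
    for axis, e in enumerate(edges):
        ax = np.searchsorted(e, cv[:, axis], side="right") - 1
        # samples exactly on the last edge belong to the last bin
        ax = np.where(cv[:, axis] == e[-1], len(e) - 2, ax)
        in_grid &= (ax >= 0) & (ax < len(e) - 1)
        multi.append(np.clip(ax, 0, len(e) - 2))
    flat = np.ravel_multi_index(multi, shape)
    return flat, in_grid


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.exp(x - m).sum()))


def free_energy(
    surface: FreeEnergySurface, cap: float = DEFAULT_CAP
) -> FreeEnergySurface:
    """Fill the free energy F = -kT ln P, min-shifted and display-capped.

    Empty bins and values at or above ``cap`` kcal/mol from the global
    minimum are reported at the cap.
    """
    P = surface.P
    occ = P > 0
    if not np.any(occ):
        raise ValueError("all-zero probability surface")
    F = np.full(P.shape, np.inf)
    F[occ] = -surface.kT * np.log(P[occ])
    F -= F[occ].min()
    F = np.minimum(F, cap)
    surface.F = F
    surface.cap = float(cap)
    return surface
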