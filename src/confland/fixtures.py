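"""Deterministic synthetic data: the module that makes everything testable.

Three generator families, each with an exactly known answer:

* exact Euclidean point configurations with their distance matrices — the
  oracle for classical MDS and the out-of-sample extension (a Euclidean
  distance matrix must embed perfectly, with zero strain);
* multi-state toy polymer ensembles — linear CA chains displaced along
  low-frequency fields orthogonal to the rigid-body modes, so inter-state
  separation is a controllable knob and intra-state spread is pure
  isotropic noise.  These stand in for crystal-structure ensembles
  (anchors = conformational states) and MD frames (noisy copies);
* boosted double-well samples — 1-D two-state Boltzmann samples drawn
  from an analytically boosted density with per-sample boost energies,
  giving the reweighting machinery an exact unbiasing target.

Seeds are mandatory arguments; no generator touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import distance_matrix

from .geometry import DissimilarityMatrix
from .structure_io import CoordinateSet, ResidueSelection

__all__ = [
    "ToyEnsembleSpec",
    "make_euclidean_config",
    "line_config_034",
    "toy_selection",
    "make_toy_ensemble",
    "make_interpolation_path",
    "make_boosted_double_well",
    "write_multi_model_pdb",
]

@dataclass(frozen=True)
class ToyEnsembleSpec:
    """Parameters of a multi-state toy ensemble.

    ``inter_state_displacement`` is the RMS per-atom displacement between
    a state anchor and the base chain (Angstrom); ``noise_sd`` the
    per-coordinate Gaussian noise within a state.  A preset is
    "separable" when displacement > 6 * noise_sd.
    """

    n_states: int = 3
    frames_per_state: int = 30
    n_atoms: int = 40
    inter_state_displacement: float = 3.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.frames_per_state < 1 or self.n_atoms < 4:
            raise ValueError("invalid ensemble spec")
        if self.inter_state_displacement < 0 or self.noise_sd < 0:
            raise ValueError("displacement and noise must be non-negative")

    @property
    def separable(self) -> bool:
        return self.inter_state_displacement > 6 * self.noise_sd


def make_euclidean_config(
    n: int, d: int, seed: int
) -> tuple[np.ndarray, DissimilarityMatrix]:
    """Random points in R^d with their exact Euclidean distance matrix."""
    if not n > d >= 1:
        raise ValueError("need n > d >= 1")
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(n, d))
    D = distance_matrix(points, points)
    labels = [f"pt{i}" for i in range(n)]
    return points, DissimilarityMatrix(labels=labels, D=D)


def line_config_034() -> tuple[np.ndarray, DissimilarityMatrix]:
    """The hand-checkable 1-D configuration {0, 3, 4}.

    Centered coordinates are (-7/3, 2/3, 5/3); double centering its
    squared distance matrix gives a Gram matrix with diagonal
    (49/9, 4/9, 25/9).
    """
    points = np.array([[0.0], [3.0], [4.0]])
    D = distance_matrix(points, points)
    return points, DissimilarityMatrix(labels=["p0", "p3", "p4"], D=D)


def toy_selection(n_atoms: int) -> ResidueSelection:
    """Selection matching the toy chain: residues 1..n, CA only."""
    return ResidueSelection(
        segments=((1, n_atoms),), atom_names=("CA",), name="toy_chain"
    )


def _base_chain(n_atoms: int) -> np.ndarray:
    """Gently helical CA chain: chiral and non-planar, so rigid fits are
    well-conditioned and mirror images are distinguishable."""
    j = np.arange(n_atoms)
    phase = 2 * np.pi * j / 10.0
    return np.column_stack(
        [3.4 * j, 2.0 * np.cos(phase), 2.0 * np.sin(phase)]
    )


def _rigid_modes(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes, flattened to 3n."""
    n = base.shape[0]
    centered = base - base.mean(axis=0)
    modes = []
    for axis in range(3):  # translations
        m = np.zeros((n, 3))
        m[:, axis] = 1.0
        modes.append(m.ravel())
    for axis in range(3):  # infinitesimal rotations
        e = np.zeros(3)
        e[axis] = 1.0
        modes.append(np.cross(centered, e).ravel())
    basis = []
    for m in modes:
        for b in basis:
            m = m - (m @ b) * b
        norm = np.linalg.norm(m)
        if norm > 1e-12:
            basis.append(m / norm)
    return np.asarray(basis)


def _state_fields(n_atoms: int, n_fields: int) -> np.ndarray:
    """Unit-RMS displacement fields orthogonal to rigid modes and each other.

    Each field mixes distinct sine/cosine frequencies on the y and z axes,
    so no two fields are related by a rotation of the chain and none can
    be absorbed by the rigid superposition.
    """
    base = _base_chain(n_atoms)
    rigid = _rigid_modes(base)
    j = (np.arange(n_atoms) + 0.5) / n_atoms
    fields = []
    k = 0
    while len(fields) < n_fields:
        k += 1
        raw = np.zeros((n_atoms, 3))
        raw[:, 1] = np.sin(2 * np.pi * (k + 1) * j)
        raw[:, 2] = 0.5 * np.cos(2 * np.pi * (k + 2) * j)
        v = raw.ravel()
        for b in rigid:
            v = v - (v @ b) * b
        for f in fields:
            v = v - (v @ f) * f
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            continue
        fields.append(v / norm)
    # scale so the RMS per-atom displacement is exactly 1 Angstrom
    return np.asarray(fields).reshape(n_fields, n_atoms, 3) * np.sqrt(n_atoms)


def make_state_anchors(spec: ToyEnsembleSpec) -> np.ndarray:
    """``n_states x n_atoms x 3`` anchor conformations of the toy chain."""
    base = _base_chain(spec.n_atoms)
    anchors = np.repeat(base[None], spec.n_states, axis=0)
    if spec.n_states > 1:
        fields = _state_fields(spec.n_atoms, spec.n_states - 1)
        for s in range(1, spec.n_states):
            anchors[s] = base + spec.inter_state_displacement * fields[s - 1]
    return anchors


def make_toy_ensemble(
    spec: ToyEnsembleSpec,
) -> tuple[list[CoordinateSet], np.ndarray]:
    """Noisy frames around each state anchor, plus true state labels.

    Returns ``(frames, state_labels)``; frame ``s{state}_f{i}`` is its
    state's anchor plus isotropic Gaussian noise of sd ``noise_sd``.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    anchors = make_state_anchors(spec)
    index = toy_selection(spec.n_atoms).atom_index()
    frames: list[CoordinateSet] = []
    labels = []
    for s in range(spec.n_states):
        for i in range(spec.frames_per_state):
            noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_atoms, 3))
            frames.append(
                CoordinateSet(
                    label=f"s{s}_f{i}", coords=anchors[s] + noise, atom_index=index
                )
            )
            labels.append(s)
    return frames, np.asarray(labels)


def make_interpolation_path(
    spec: ToyEnsembleSpec, n_points: int = 20
) -> list[CoordinateSet]:
    """Noise-free frames interpolating linearly from state 0 to state 1."""
    if spec.n_states < 2:
        raise ValueError("path needs at least two states")
    anchors = make_state_anchors(spec)
    index = toy_selection(spec.n_atoms).atom_index()
    ts = np.linspace(0.0, 1.0, n_points)
    return [
        CoordinateSet(
            label=f"path_{i}",
            coords=(1 - t) * anchors[0] + t * anchors[1],
            atom_index=index,
        )
        for i, t in enumerate(ts)
    ]


def make_boosted_double_well(
    n: int,
    kT: float,
    dF: float,
    boost: str | Callable[[np.ndarray], np.ndarray] = "amd",
    seed: int = 0,
    sigma: float = 0.35,
    grid_points: int = 8001,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Samples from a boosted two-state distribution with analytic targets.

    The unbiased density is a two-Gaussian mixture with wells at x = -1
    and x = +1 and population free-energy difference ~``dF`` (kcal/mol).
    ``boost`` is ``"none"`` (dV = 0), ``"amd"`` (the accelerated-MD form
    dV = (E-U)^2/(alpha+E-U) below the barrier energy E) or any callable
    returning non-negative boost energies.  Samples are drawn from the
    boosted density exp(-(U+dV)/kT) by inverse-CDF on a fine grid.

    Returns ``(x, deltaV, dF_true)`` where ``dF_true`` is the exact
    free-energy difference between the x>0 and x<0 wells of the unbiased
    law, computed by quadrature (the recovery target).
    """
    if n <= 0 or kT <= 0:
        raise ValueError("need n > 0 and kT > 0")
    x = np.linspace(-3.0, 3.0, grid_points)
    # mixture potential: left well at -1, right well at +1 offset by dF
    logp = np.logaddexp(
        -((x + 1.0) ** 2) / (2 * sigma**2),
        -dF / kT - ((x - 1.0) ** 2) / (2 * sigma**2),
    )
    U = -kT * logp

    if boost == "none":
        dV = np.zeros_like(x)
    elif boost == "amd":
        i0 = np.argmin(np.abs(x))
        E = U[i0]  # boost up to the barrier top
        alpha = 2.0 * kT
        gap = np.clip(E - U, 0.0, None)
        dV = gap**2 / (alpha + gap)
    elif callable(boost):
        dV = np.asarray(boost(x), dtype=float)
        if np.any(dV < 0):
            raise ValueError("boost must be non-negative")
    else:
        raise ValueError(f"unknown boost spec {boost!r}")

    p_unb = np.exp(-(U - U.min()) / kT)
    p_unb /= np.trapezoid(p_unb, x)
    left = x < 0
    dF_true = float(
        -kT * np.log(np.trapezoid(p_unb[~left], x[~left]) / np.trapezoid(p_unb[left], x[left]))
    )

    Ub = U + dV
    p_b = np.exp(-(Ub - Ub.min()) / kT)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p_b[1:] + p_b[:-1]) * np.diff(x))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    xs = np.interp(u, cdf, x)
    dVs = np.interp(xs, x, dV)
    return xs, dVs, dF_true


def write_multi_model_pdb(
    sets: Sequence[CoordinateSet], path: str | Path
) -> None:
    """Write coordinate sets as models of one multi-model PDB file.

    Each ``(residue number, atom name)`` entry becomes an atom of an ALA
    residue in chain A, which lets the full file-based pipeline (parse,
    filter, extract, embed) run on synthetic ensembles.
    """
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("toy")
    for m, cset in enumerate(sets):
        builder.init_model(m, m + 1)
        builder.init_chain("A")
        builder.init_seg("    ")
        current_res = None
        for (resnum, atom_name), xyz in zip(cset.atom_index, cset.coords):
            if resnum != current_res:
                builder.init_residue("ALA", " ", resnum, " ")
                current_res = resnum
            builder.init_atom(
                atom_name,
                np.asarray(xyz, dtype=float),
                0.0,
                1.0,
                " ",
                atom_name.center(4),
                element=atom_name[0],
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
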