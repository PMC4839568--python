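"""Per-frame structural order parameters for kinase conformational states.

Complements the landscape projection with the classical kinase
observables: charged-group minimum distances (e.g. the Lys33-Glu51 salt
bridge of the active state versus the Glu51-Arg150 interaction of the
Src-like inactive state), activation-loop and alphaC-helix RMSDs against
a reference conformation, hydrogen-bond detection/occupancy and pi-pi
ring-interaction classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import optimal_superposition
from .structure_io import CoordinateSet, ResidueSelection, StructureRecord

__all__ = [
    "ContactPair",
    "HBondCriteria",
    "PiPiCriteria",
    "GLU_ACID_ATOMS",
    "LYS_AMINE_ATOMS",
    "ARG_GUANIDINIUM_ATOMS",
    "A_LOOP",
    "ALPHA_C",
    "pair_min_distance",
    "salt_bridge_difference",
    "segment_rmsd",
    "detect_hbond",
    "hbond_occupancy",
    "classify_pipi",
    "order_parameter_table",
]

# Charged-group atom sets used for salt-bridge minimum distances.
GLU_ACID_ATOMS = ("OE1", "OE2")
LYS_AMINE_ATOMS = ("NZ",)
ARG_GUANIDINIUM_ATOMS = ("NE", "NH1", "NH2")

#: Activation loop, DFG through APE (CDK2 numbering); override per system.
A_LOOP = ResidueSelection(segments=((145, 172),), name="a_loop")
#: alphaC helix (CDK2 numbering).
ALPHA_C = ResidueSelection(segments=((46, 55),), name="alpha_c")


@dataclass(frozen=True)
class ContactPair:
    """A donor/acceptor residue pair with candidate atom-name sets."""

    donor_res: int
    donor_atoms: tuple[str, ...]
    acceptor_res: int
    acceptor_atoms: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.donor_atoms or not self.acceptor_atoms:
            raise ValueError("atom sets must be non-empty")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition: D-A cutoff and D-H...A angle."""

    max_DA_distance: float = 3.5  # Angstrom
    min_DHA_angle: float = 120.0  # degrees

    def __post_init__(self) -> None:
        if self.max_DA_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_DHA_angle <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class PiPiCriteria:
    """Ring-interaction windows: plane angle and centroid distance."""

    ftf_max_angle: float = 30.0   # face-to-face: plane angle below this ...
    ftf_max_dist: float = 4.4     # ... and centroids closer than this (A)
    etf_angle_range: tuple[float, float] = (60.0, 120.0)  # edge-to-face
    etf_max_dist: float = 5.5


def _residue_atoms(
    frame: StructureRecord, resnum: int, names: Iterable[str]
) -> np.ndarray:
    coords = [
        xyz for name in names if (xyz := frame.get_atom(resnum, name)) is not None
    ]
    if not coords:
        raise KeyError(
            f"{frame.id}: residue {resnum} has none of the atoms {tuple(names)}"
        )
    return np.asarray(coords)


def pair_min_distance(frame: StructureRecord, pair: ContactPair) -> float:
    """Minimum donor-atom x acceptor-atom Euclidean distance (Angstrom)."""
    donors = _residue_atoms(frame, pair.donor_res, pair.donor_atoms)
    acceptors = _residue_atoms(frame, pair.acceptor_res, pair.acceptor_atoms)
    diff = donors[:, None, :] - acceptors[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())


def salt_bridge_difference(
    frame: StructureRecord,
    glu: int = 51,
    lys: int = 33,
    arg: int = 150,
) -> float:
    """d(Glu-Arg) - d(Lys-Glu) over charged-group atoms (Angstrom).

    The sign separates the two salt-bridge patterns of the conserved
    alphaC glutamate: it engages the catalytic lysine in the active state
    and the activation-loop arginine in the Src-like inactive state.
    """
    d_glu_arg = pair_min_distance(
        frame,
        ContactPair(glu, GLU_ACID_ATOMS, arg, ARG_GUANIDINIUM_ATOMS, "glu-arg"),
    )
    d_lys_glu = pair_min_distance(
        frame,
        ContactPair(lys, LYS_AMINE_ATOMS, glu, GLU_ACID_ATOMS, "lys-glu"),
    )
    return d_glu_arg - d_lys_glu


def segment_rmsd(
    frame: CoordinateSet,
    reference: CoordinateSet,
    core: ResidueSelection,
    segment: ResidueSelection,
) -> float:
    """Segment RMSD after superposing on the core, without refitting.

    The frame is rigidly fitted to the reference over ``core`` atoms, the
    resulting transform is applied to the frame's ``segment`` atoms, and
    the RMSD against the reference segment is returned.
    """
    R, t, _ = optimal_superposition(frame.subset(core), reference.subset(core))
    seg_frame = frame.subset(segment).coords @ R.T + t
    seg_ref = reference.subset(segment).coords
    diff = seg_frame - seg_ref
    return float(np.sqrt((diff**2).sum() / len(seg_ref)))


def detect_hbond(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
) -> bool:
    """True iff |D-A| <= cutoff and the D-H...A angle exceeds the minimum."""
    d = np.asarray(donor, float)
    h = np.asarray(hydrogen, float)
    a = np.asarray(acceptor, float)
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("coincident atoms: D-H...A angle undefined")
    if np.linalg.norm(d - a) > criteria.max_DA_distance:
        return False
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    return bool(angle > criteria.min_DHA_angle)


def hbond_occupancy(flags: Sequence[bool]) -> float:
    """Percent of frames in which the bond is formed."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty series")
    return float(100.0 * flags.mean())


def _ring_plane(ring: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a least-squares plane through the ring."""
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[0] < 3 or ring.shape[1] != 3:
        raise ValueError("ring needs at least 3 points in 3D")
    centroid = ring.mean(axis=0)
    centered = ring - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("collinear ring atoms: plane undefined")
    return centroid, vt[2]


def classify_pipi(
    ring1: np.ndarray,
    ring2: np.ndarray,
    criteria: PiPiCriteria = PiPiCriteria(),
) -> str:
    """Classify an aromatic ring pair: face_to_face, edge_to_face or none.

    The inter-plane angle is folded to [0, 90] degrees before testing (a
    plane has no orientation), so the edge-to-face 60-120 degree window is
    equivalent to 60-90.  Face-to-face is tested first.
    """
    c1, n1 = _ring_plane(np.asarray(ring1, float))
    c2, n2 = _ring_plane(np.asarray(ring2, float))
    dist = float(np.linalg.norm(c1 - c2))
    cosang = np.clip(abs(n1 @ n2), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(cosang)))  # folded to [0, 90]

    if angle < criteria.ftf_max_angle and dist < criteria.ftf_max_dist:
        return "face_to_face"
    lo, hi = criteria.etf_angle_range
    lo_folded = min(lo, 180 - hi) if hi > 90 else lo
    if lo_folded <= angle <= 90.0 and dist < criteria.etf_max_dist:
        return "edge_to_face"
    return "none"


def order_parameter_table(
    frames: Sequence[StructureRecord],
    frame_sets: Sequence[CoordinateSet],
    reference_set: CoordinateSet,
    core: ResidueSelection,
    segments: dict[str, ResidueSelection] | None = None,
    times: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-frame order-parameter channels as a tidy table.

    Columns: frame, time, the salt-bridge distance difference and one
    ``rmsd_<name>_A`` column per segment (all distances in Angstrom).
    ``frames`` supplies side-chain atoms for the salt bridges;
    ``frame_sets``/``reference_set`` supply the backbone core used for the
    segment RMSD superposition.
    """
    if segments is None:
        segments = {"a_loop": A_LOOP, "alpha_c": ALPHA_C}
    if len(frames) != len(frame_sets):
        raise ValueError("frames and frame_sets must align")
    rows = []
    for i, (rec, cset) in enumerate(zip(frames, frame_sets)):
        row: dict[str, float] = {
            "frame": i,
            "time": float(times[i]) if times is not None else float(i),
            "salt_bridge_diff_A": salt_bridge_difference(rec),
        }
        for name, seg in segments.items():
            row[f"rmsd_{name}_A"] = segment_rmsd(cset, reference_set, core, seg)
        rows.append(row)
    return pd.DataFrame(rows)
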