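"""Reading protein coordinate files and extracting curated backbone cores.

A conformational-landscape analysis starts from an ensemble of crystal
structures of the same protein.  This module parses PDB-format files into
light-weight :class:`StructureRecord` objects, applies the dataset-curation
filters (resolution cutoff, completeness of the fitted residue core) and
extracts fixed-order backbone coordinate sets for a named residue selection
so that every structure contributes an identically indexed point cloud to
the downstream RMSD machinery.

The CDK2 conserved-core selection (12 secondary-structure segments, human
CDK2 numbering) ships as the preset :data:`CDK2_CORE`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import yaml
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

__all__ = [
    "ResidueSelection",
    "StructureRecord",
    "CoordinateSet",
    "CDK2_CORE",
    "BACKBONE_ATOMS",
    "load_structure",
    "iter_models",
    "filter_dataset",
    "extract_core_coordinates",
    "load_selection_presets",
]

#: Standard backbone heavy atoms.  The carbonyl oxygen is included by
#: default because it adds peptide-plane orientation signal; pass a custom
#: ``atom_names`` to restrict to (N, CA, C) or CA-only selections.
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class ResidueSelection:
    """An ordered set of inclusive residue-number ranges plus atom names.

    Parameters
    ----------
    segments
        Inclusive ``(start, end)`` residue-number ranges, sorted and
        non-overlapping.
    atom_names
        Atom names extracted per residue, in order.
    name
        Preset label used in reports and serialized models.
    """

    segments: tuple[tuple[int, int], ...]
    atom_names: tuple[str, ...] = BACKBONE_ATOMS
    name: str = "custom"

    def __post_init__(self) -> None:
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        if not self.atom_names:
            raise ValueError("atom_names must be non-empty")
        for start, end in segs:
            if end < start:
                raise ValueError(f"segment ({start}, {end}) has end < start")
        for (_, e0), (s1, _) in zip(segs, segs[1:]):
            if s1 <= e0:
                raise ValueError("segments must be sorted and non-overlapping")

    @property
    def residue_numbers(self) -> tuple[int, ...]:
        """All selected residue numbers, in ascending segment order."""
        return tuple(
            num for start, end in self.segments for num in range(start, end + 1)
        )

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    @property
    def n_atoms(self) -> int:
        return self.n_residues * len(self.atom_names)

    def atom_index(self) -> tuple[tuple[int, str], ...]:
        """Canonical ``(residue number, atom name)`` extraction order."""
        return tuple(
            (num, atom)
            for num in self.residue_numbers
            for atom in self.atom_names
        )


#: Conserved-core selection for human CDK2: beta1-beta5 strands, the
#: alphaC/alphaD/alphaE/alphaF/alphaI helices, the catalytic loop and the
#: DFG-containing segment, in CDK2 numbering.
CDK2_CORE = ResidueSelection(
    segments=(
        (4, 12),     # beta1
        (17, 24),    # beta2
        (29, 34),    # beta3
        (46, 55),    # alphaC
        (66, 71),    # beta4
        (76, 81),    # beta5
        (87, 93),    # alphaD
        (101, 120),  # alphaE
        (121, 135),  # catalytic loop
        (140, 150),  # includes DFG
        (182, 194),  # alphaF
        (277, 282),  # alphaI
    ),
    atom_names=BACKBONE_ATOMS,
    name="cdk2_core",
)


@dataclass
class StructureRecord:
    """One chain of one coordinate file.

    ``residues`` maps ``(residue number, insertion code)`` to an atom-name ->
    coordinate table.  Residues carrying an insertion code are kept distinct
    and never match plain-numbered selections, which avoids silent
    misalignment of renumbered loops.
    """

    id: str
    chain_id: str
    residues: dict[tuple[int, str], dict[str, np.ndarray]]
    resolution: float | None = None

    def __post_init__(self) -> None:
        for key, atoms in self.residues.items():
            for name, xyz in atoms.items():
                arr = np.asarray(xyz, dtype=float)
                if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                    raise ValueError(
                        f"{self.id}: residue {key} atom {name} has invalid coordinates"
                    )
                atoms[name] = arr

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def get_atom(self, resnum: int, atom_name: str) -> np.ndarray | None:
        """Coordinate of ``atom_name`` in plain-numbered residue ``resnum``."""
        atoms = self.residues.get((resnum, ""))
        if atoms is None:
            return None
        return atoms.get(atom_name)

    def has_selection(self, selection: ResidueSelection) -> bool:
        """True if every selected residue/atom is present (exactly once)."""
        return all(
            self.get_atom(num, atom) is not None
            for num, atom in selection.atom_index()
        )


@dataclass
class CoordinateSet:
    """An ``m x 3`` coordinate block in fixed ``(residue, atom)`` order.

    Two CoordinateSets built from the same :class:`ResidueSelection` share
    an identical ``atom_index`` and are therefore directly superposable.
    """

    label: str
    coords: np.ndarray
    atom_index: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_index = tuple((int(n), str(a)) for n, a in self.atom_index)
        if self.coords.shape != (len(self.atom_index), 3):
            raise ValueError(
                f"{self.label}: coords shape {self.coords.shape} does not match "
                f"atom_index length {len(self.atom_index)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.label}: non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_index)

    def subset(self, selection: ResidueSelection) -> "CoordinateSet":
        """Rows of this set that fall inside ``selection``.

        Raises ``KeyError`` if any selected atom is absent.
        """
        index = {pair: i for i, pair in enumerate(self.atom_index)}
        wanted = selection.atom_index()
        if not wanted:
            raise ValueError("empty selection")
        rows = []
        for pair in wanted:
            if pair not in index:
                raise KeyError(
                    f"{self.label}: residue {pair[0]} atom {pair[1]} "
                    "not present in coordinate set"
                )
            rows.append(index[pair])
        return CoordinateSet(self.label, self.coords[rows], wanted)


def _resolve_altloc(atom) -> np.ndarray | None:
    # Disordered atoms: keep the blank altloc if present, else altloc "A";
    # any other lone altloc is treated as unresolved.
    if atom.is_disordered():
        ids = atom.disordered_get_id_list()
        for want in (" ", "A"):
            if want in ids:
                return np.asarray(atom.disordered_get(want).get_coord(), float)
        return None
    if atom.get_altloc() not in (" ", "A"):
        return None
    return np.asarray(atom.get_coord(), dtype=float)


def _chain_to_record(
    chain, struct_id: str, resolution: float | None
) -> StructureRecord:
    residues: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    for residue in chain:
        hetflag, resnum, icode = residue.get_id()
        if hetflag.strip():
            continue  # waters / heteroatoms
        key = (int(resnum), icode.strip())
        atoms: dict[str, np.ndarray] = {}
        for atom in residue:
            xyz = _resolve_altloc(atom)
            if xyz is not None:
                atoms[atom.get_name()] = xyz
        if atoms:
            residues[key] = atoms
    return StructureRecord(
        id=struct_id, chain_id=chain.id, residues=residues, resolution=resolution
    )


def _pick_chain(model, chain: str | None):
    if chain is not None:
        if chain not in model:
            raise ValueError(
                f"chain {chain!r} absent; available: "
                f"{[c.id for c in model]}"
            )
        return model[chain]
    # default: first chain containing amino-acid residues
    for cand in model:
        if any(is_aa(res, standard=False) for res in cand):
            return cand
    chains = list(model)
    if not chains:
        raise ValueError("file contains no chains")
    return chains[0]


def load_structure(
    path: str | Path,
    chain: str | None = None,
    *,
    id: str | None = None,
    resolution: float | None = None,
) -> StructureRecord:
    """Parse a PDB-format file into a :class:`StructureRecord`.

    Parameters
    ----------
    path
        PDB-format coordinate file.
    chain
        Chain identifier; defaults to the first protein chain.
    id
        Record label; defaults to the file stem.
    resolution
        Overrides the resolution parsed from the header (useful for files
        whose REMARK records were stripped).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(id or path.stem, str(path))
    if resolution is None:
        resolution = structure.header.get("resolution")
    model = next(iter(structure))
    picked = _pick_chain(model, chain)
    return _chain_to_record(picked, id or path.stem, resolution)


def iter_models(
    path: str | Path,
    chain: str | None = None,
    *,
    id: str | None = None,
) -> Iterator[StructureRecord]:
    """Yield one :class:`StructureRecord` per MODEL of a multi-model PDB.

    Records are labelled ``<id>:<model serial>``; this is the trajectory
    reader for frames stored as multi-model PDB.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(id or path.stem, str(path))
    base = id or path.stem
    for model in structure:
        picked = _pick_chain(model, chain)
        yield _chain_to_record(picked, f"{base}:{model.serial_num}", None)


def filter_dataset(
    records: Sequence[StructureRecord],
    selection: ResidueSelection,
    max_resolution: float = 2.5,
) -> list[StructureRecord]:
    """Dataset-curation filter: resolution and core completeness.

    Retains records whose resolution is known and ``<= max_resolution``
    (the cutoff is inclusive) and in which every residue/atom of
    ``selection`` is unambiguously present.  Input order is preserved and
    the operation is idempotent.
    """
    if max_resolution <= 0:
        raise ValueError("max_resolution must be positive")
    return [
        rec
        for rec in records
        if rec.resolution is not None
        and rec.resolution <= max_resolution
        and rec.has_selection(selection)
    ]


def extract_core_coordinates(
    record: StructureRecord, selection: ResidueSelection
) -> CoordinateSet:
    """Extract the selection's atoms in canonical order.

    Raises ``KeyError`` naming the first missing residue/atom; raises
    ``ValueError`` for an empty selection.
    """
    index = selection.atom_index()
    if not index:
        raise ValueError("empty selection")
    coords = np.empty((len(index), 3), dtype=float)
    for i, (num, atom) in enumerate(index):
        xyz = record.get_atom(num, atom)
        if xyz is None:
            raise KeyError(
                f"{record.id}: residue {num} atom {atom} missing from structure"
            )
        coords[i] = xyz
    return CoordinateSet(label=record.id, coords=coords, atom_index=index)


def load_selection_presets(path: str | Path) -> dict[str, ResidueSelection]:
    """Read selection presets from a YAML or JSON config file.

    Expected layout::

        selections:
          my_core:
            segments: [[4, 12], [17, 24]]
            atom_names: [N, CA, C, O]

    The CDK2 core preset is always available under ``cdk2_core``.
    """
    path = Path(path)
    text = path.read_text()
    data: Mapping = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    presets: dict[str, ResidueSelection] = {"cdk2_core": CDK2_CORE}
    for name, entry in (data.get("selections") or {}).items():
        presets[name] = ResidueSelection(
            segments=tuple(tuple(seg) for seg in entry["segments"]),
            atom_names=tuple(entry.get("atom_names", BACKBONE_ATOMS)),
            name=name,
        )
    return presets
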