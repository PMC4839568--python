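import numpy as np
import pytest

from confland.structure_io import (
    CDK2_CORE,
    ResidueSelection,
    StructureRecord,
)


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    altloc: str = " ",
    occupancy: float = 1.0,
) -> str:
    """One fixed-width PDB ATOM record."""
    element = name.strip()[0]
    name_fmt = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_fmt}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_tripeptide_pdb(path, resolution: float | None = 2.0) -> None:
    """A hand-written 3-residue backbone-only PDB file."""
    lines = ["HEADER    TEST PROTEIN                            01-JAN-20   XXXX"]
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {resolution:7.2f} ANGSTROMS.")
    serial = 1
    for i, resnum in enumerate((1, 2, 3)):
        for j, name in enumerate(("N", "CA", "C", "O")):
            lines.append(
                atom_line(serial, name, "ALA", "A", resnum, 3.8 * i + j, 0.5 * j, 0.0)
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def make_record(
    selection: ResidueSelection,
    rec_id: str = "synth",
    resolution: float | None = 2.0,
    rng: np.random.Generator | None = None,
    drop: tuple[int, str] | None = None,
) -> StructureRecord:
    """Synthetic in-memory record covering a whole selection.

    ``drop`` removes one (residue, atom) to exercise completeness checks.
    """
    rng = rng or np.random.default_rng(0)
    residues = {}
    for num in selection.residue_numbers:
        atoms = {
            name: rng.normal(size=3) + np.array([num * 3.0, 0.0, 0.0])
            for name in selection.atom_names
        }
        residues[(num, "")] = atoms
    if drop is not None:
        num, name = drop
        del residues[(num, "")][name]
    return StructureRecord(
        id=rec_id, chain_id="A", residues=residues, resolution=resolution
    )


@pytest.fixture
def cdk2_selection():
    return CDK2_CORE


@pytest.fixture
def rng():
    return np.random.default_rng(42)
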