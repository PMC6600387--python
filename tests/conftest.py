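"""Shared fixtures: handcrafted PDB text and small benchmark objects."""

from __future__ import annotations

import numpy as np
import pytest

from covbench.datamodel import (
    AnchorResidue,
    BenchmarkEntry,
    LigandPose,
    StructureContext,
)
from covbench.warhead import WarheadTaxonomy


def pdb_atom(serial: int, name: str, resname: str, chain: str, resnum: int,
             xyz, element: str, het: bool = False) -> str:
    record = "HETATM" if het else "ATOM  "
    x, y, z = xyz
    aname = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:5d} {aname:4s} {resname:<3s} {chain}"
            f"{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n")


def pdb_link(name1: str, res1: str, chain1: str, num1: int,
             name2: str, res2: str, chain2: str, num2: int) -> str:
    a1 = f" {name1:<3s}" if len(name1) < 4 else name1
    a2 = f" {name2:<3s}" if len(name2) < 4 else name2
    return (f"LINK        {a1:4s} {res1:<3s} {chain1}{num1:4d}"
            f"{'':16s}{a2:4s} {res2:<3s} {chain2}{num2:4d}   "
            f"  1555   1555  1.80\n")


CYS_ATOMS = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("CA", "C", (1.46, 0.00, 0.00)),
    ("C", "C", (2.00, 1.42, 0.00)),
    ("O", "O", (1.25, 2.39, 0.00)),
    ("CB", "C", (2.00, -0.77, 1.21)),
    ("SG", "S", (3.80, -0.90, 1.25)),
]

# a 5-heavy-atom ligand whose C1 sits one S-C bond from the SG above
LIG_ATOMS = [
    ("C1", "C", (5.61, -0.90, 1.25)),
    ("C2", "C", (6.31, -0.90, 2.55)),
    ("C3", "C", (7.83, -0.90, 2.40)),
    ("O1", "O", (6.91, -0.90, 0.25)),
    ("N1", "N", (8.43, -0.90, 3.70)),
]


def covalent_pdb(include_link: bool = True, anchor_res: str = "CYS",
                 link_atom: str = "SG", shift=(0.0, 0.0, 0.0),
                 extra: str = "", resolution: float = 2.0) -> str:
    """Minimal single-chain covalent complex as PDB text."""
    lines = [
        "HEADER    TEST COMPLEX                            01-JAN-20   1TST\n",
        f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.\n",
    ]
    if include_link:
        lines.append(pdb_link(link_atom, anchor_res, "A", 25,
                              "C1", "LIG", "A", 900))
    serial = 1
    atoms = CYS_ATOMS if anchor_res == "CYS" else [
        (n.replace("SG", "NZ"), e.replace("S", "N"), xyz)
        for n, e, xyz in CYS_ATOMS]
    for name, element, xyz in atoms:
        lines.append(pdb_atom(serial, name, anchor_res, "A", 25,
                              xyz, element))
        serial += 1
    for name, element, xyz in LIG_ATOMS:
        pos = tuple(np.asarray(xyz) + np.asarray(shift))
        lines.append(pdb_atom(serial, name, "LIG", "A", 900, pos,
                              element, het=True))
        serial += 1
    lines.append(extra)
    lines.append("END\n")
    return "".join(lines)


@pytest.fixture(scope="session")
def taxonomy() -> WarheadTaxonomy:
    return WarheadTaxonomy.default()


def make_simple_entry(entry_id: str = "e1", resolution: float = 2.0,
                      anchor_name: str = "CYS", n_linkages: int = 1,
                      has_nucleic: bool = False,
                      cofactor_distance: float = np.inf,
                      ligand_smiles: str | None = None,
                      **kw) -> BenchmarkEntry:
    """In-memory entry for filter tests; ligand defaults to a 6-heavy chain."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    link = "SG" if anchor_name == "CYS" else "OG"
    anchor = AnchorResidue(
        chain="A", residue_number=25, residue_name=anchor_name,
        link_atom=link,
        atoms={n: np.asarray(x)
               for n, _, x in CYS_ATOMS} if anchor_name == "CYS" else
              {"N": np.zeros(3), "CA": np.array([1.46, 0, 0]),
               "CB": np.array([2.0, -0.77, 1.21]),
               "OG": np.array([3.4, -0.87, 1.24])})
    smiles = ligand_smiles or "CCCCCO"
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 11
    AllChem.EmbedMolecule(mol, params)
    mol = Chem.RemoveHs(mol)
    pose = LigandPose.from_rdkit(mol)
    return BenchmarkEntry(
        entry_id=entry_id,
        anchor=anchor,
        reference_ligand=pose,
        pre_reaction_ligand=mol,
        resolution=resolution,
        context=StructureContext(
            has_nucleic_chains=has_nucleic,
            cofactor_min_distance=cofactor_distance,
            n_covalent_linkages=n_linkages),
        **kw,
    )
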