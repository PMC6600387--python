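"""Core domain types and file I/O for covalent-docking benchmarks.

The toolkit evaluates *covalent* docking runs: the ligand is chemically
bonded to a receptor residue (a cysteine S-gamma or serine O-gamma), so a
benchmark entry couples a receptor structure, the identity of that anchor
residue, and the crystallographic ligand pose that docked poses are judged
against.  Structures are read with gemmi (PDB/mmCIF), small molecules with
RDKit (SDF/MOL/MOL2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdDetermineBonds

__all__ = [
    "AnchorResidue",
    "LigandPose",
    "BenchmarkEntry",
    "DockingRun",
    "StructureContext",
    "NotCovalentError",
    "UnsupportedAnchorError",
    "read_complex",
    "read_pose_file",
    "write_pose_file",
    "write_results",
    "read_metadata",
]

# Covalent-linkage distance fallback: bond declared when a ligand heavy atom
# lies within these cutoffs of the anchor side-chain atom (S-C ~1.8 A,
# O-C ~1.4 A, plus tolerance).
LINK_CUTOFF = {"SG": 2.0, "OG": 1.8}

ANCHOR_ATOM = {"CYS": "SG", "SER": "OG"}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_NUCLEIC_NAMES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
_METAL_ELEMENTS = {
    "LI", "NA", "K", "RB", "CS", "MG", "CA", "SR", "BA", "MN", "FE", "CO",
    "NI", "CU", "ZN", "CD", "HG", "AL", "GA", "PT", "PD", "AG", "AU", "W",
    "MO", "V", "CR",
}


class NotCovalentError(ValueError):
    """No covalent linkage between the named ligand and a Cys/Ser residue."""


class UnsupportedAnchorError(ValueError):
    """A covalent linkage exists but the anchor residue is not Cys or Ser."""


@dataclass(frozen=True)
class AnchorResidue:
    """The nucleophilic receptor residue forming the covalent bond.

    ``link_atom`` is SG for cysteine and OG for serine; ``atoms`` maps
    atom names to coordinates (angstrom, deposited receptor frame).
    """

    chain: str
    residue_number: int
    residue_name: str  # CYS | SER
    link_atom: str     # SG | OG
    atoms: dict[str, np.ndarray] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.residue_name not in ANCHOR_ATOM:
            raise UnsupportedAnchorError(
                f"unsupported anchor residue {self.residue_name!r}; "
                "covalent anchors must be CYS or SER"
            )
        if self.link_atom != ANCHOR_ATOM[self.residue_name]:
            raise ValueError(
                f"link atom {self.link_atom!r} inconsistent with "
                f"{self.residue_name} (expected {ANCHOR_ATOM[self.residue_name]})"
            )

    @property
    def link_coord(self) -> np.ndarray:
        return self.atoms[self.link_atom]


@dataclass
class LigandPose:
    """One ligand conformation: elements, coordinates and bond graph.

    ``pose_rank`` is 1-based, 1 = top pose by the engine's own score
    convention. ``score_orientation`` records whether the engine's score is
    "lower_better" (e.g. an energy) or "higher_better" (e.g. a fitness).
    """

    elements: tuple[str, ...]
    coords: np.ndarray                      # (n_atoms, 3) angstrom
    bonds: tuple[tuple[int, int, float], ...] = ()
    pose_rank: int = 1
    score: float | None = None
    score_orientation: str = "lower_better"
    name: str = ""
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords must be (n_atoms, 3) matching elements")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("pose coordinates must be finite")
        if self.pose_rank < 1:
            raise ValueError("pose_rank must be >= 1")
        idx = [i for b in self.bonds for i in b[:2]]
        if idx and (min(idx) < 0 or max(idx) >= len(self.elements)):
            raise ValueError("bond indices out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, e in enumerate(self.elements) if e.upper() != "H"],
            dtype=int,
        )

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices)

    def heavy_composition(self) -> tuple[str, ...]:
        """Sorted heavy-atom element multiset, for composition checks."""
        return tuple(sorted(e.capitalize() for e in self.elements
                            if e.upper() != "H"))

    def to_rdkit(self, sanitize: bool = False) -> Chem.Mol:
        """Build an RDKit molecule carrying this conformation.

        Bond orders are taken from ``bonds``; if absent they are perceived
        from interatomic distances (deposited PDB ligands carry no bond
        records).
        """
        mol = Chem.RWMol()
        for e in self.elements:
            mol.AddAtom(Chem.Atom(e.capitalize()))
        conf = Chem.Conformer(self.n_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
        if self.bonds:
            order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                         3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
            for i, j, order in self.bonds:
                mol.AddBond(int(i), int(j),
                            order_map.get(float(order), Chem.BondType.SINGLE))
        out = mol.GetMol()
        out.AddConformer(conf, assignId=True)
        if not self.bonds:
            rdDetermineBonds.DetermineConnectivity(out)
        if sanitize:
            Chem.SanitizeMol(out, catchErrors=True)
        else:
            out.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(out)
        return out

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, conf_id: int = -1, **kw) -> "LigandPose":
        conf = mol.GetConformer(conf_id)
        elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        bonds = tuple(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        )
        return cls(elements=elements, coords=coords, bonds=bonds, **kw)


@dataclass
class StructureContext:
    """Deposited-asymmetric-unit facts recorded *before* stripping.

    Curation filters (nucleic-acid exclusion, cofactor 8 A proximity) act on
    the structure as deposited, not on the cleaned entry, so the reader
    snapshots them here.
    """

    has_nucleic_chains: bool = False
    cofactor_min_distance: float = math.inf   # A, nearest cofactor heavy atom
    cofactor_names: tuple[str, ...] = ()
    n_covalent_linkages: int = 1


@dataclass
class BenchmarkEntry:
    """One curated covalent co-crystal complex.

    ``reference_ligand`` is the crystallographic (post-reaction) pose in the
    deposited receptor frame; ``pre_reaction_ligand`` is the molecular graph
    of the ligand restored to its pre-bond form, i.e. the species an engine
    actually docks.
    """

    entry_id: str
    anchor: AnchorResidue
    reference_ligand: LigandPose
    pre_reaction_ligand: Chem.Mol | None = None
    receptor_type: str | None = None
    uniprot_id: str | None = None
    warhead_class: str | None = None
    reaction_class: str | None = None
    resolution: float | None = None
    kinase_domain: str | None = None
    context: StructureContext = field(default_factory=StructureContext)
    receptor_atoms: pd.DataFrame | None = None   # chain/resnum/resname/name/element/x/y/z
    source_path: str | None = None

    def validate(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError("resolution must be positive")
        if self.reference_ligand.n_heavy < 5:
            raise ValueError("reference ligand must have >= 5 heavy atoms")


@dataclass
class DockingRun:
    """Ordered, scored pose list produced by one tool for one entry."""

    tool_id: str
    entry_id: str
    poses: list[LigandPose]

    def __post_init__(self) -> None:
        if not self.poses:
            raise ValueError("a docking run must contain at least one pose")
        ranks = sorted(p.pose_rank for p in self.poses)
        if ranks != list(range(1, len(self.poses) + 1)):
            raise ValueError("pose ranks must be 1..n without gaps")
        self.poses = sorted(self.poses, key=lambda p: p.pose_rank)
        comp = {p.heavy_composition() for p in self.poses}
        if len(comp) > 1:
            raise ValueError("poses in a run must share heavy-atom composition")

    @property
    def top_pose(self) -> LigandPose:
        return self.poses[0]


# ---------------------------------------------------------------------------
# structure reading


def _residue_heavy_coords(res: gemmi.Residue) -> np.ndarray:
    return np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res
                     if a.element.name != "H"])


def _is_metal(res: gemmi.Residue) -> bool:
    return len(res) == 1 and res[0].element.name.upper() in _METAL_ELEMENTS


def _scan_context(st: gemmi.Structure, ligand_code: str,
                  buffer_names: set[str]) -> StructureContext:
    model = st[0]
    has_nucleic = any(
        res.name.strip() in _NUCLEIC_NAMES
        for chain in model for res in chain
    )
    lig_coords = []
    cof_atoms: list[tuple[str, np.ndarray]] = []
    for chain in model:
        for res in chain:
            name = res.name.strip()
            if name == ligand_code:
                lig_coords.append(_residue_heavy_coords(res))
            elif res.het_flag == "H" and name not in _WATER_NAMES \
                    and name not in buffer_names and not _is_metal(res) \
                    and name not in _NUCLEIC_NAMES:
                xyz = _residue_heavy_coords(res)
                if len(xyz):
                    cof_atoms.append((name, xyz))
    mind, names = math.inf, []
    if lig_coords:
        lig = np.vstack(lig_coords)
        for name, xyz in cof_atoms:
            d = np.sqrt(((xyz[:, None, :] - lig[None, :, :]) ** 2).sum(-1)).min()
            if d < mind:
                mind = float(d)
            names.append(name)
    return StructureContext(
        has_nucleic_chains=has_nucleic,
        cofactor_min_distance=mind,
        cofactor_names=tuple(sorted(set(names))),
    )


def _find_linkages_from_connections(
    st: gemmi.Structure, ligand_code: str
) -> list[tuple[str, int, str, str]]:
    """(chain, resnum, resname, protein_atom) per covalent record to ligand."""
    out = []
    for con in st.connections:
        p1, p2 = con.partner1, con.partner2
        for lig, prot in ((p1, p2), (p2, p1)):
            if lig.res_id.name.strip() == ligand_code:
                out.append((prot.chain_name, prot.res_id.seqid.num,
                            prot.res_id.name.strip(), prot.atom_name.strip()))
    return out


def _find_linkages_by_distance(
    st: gemmi.Structure, ligand_code: str
) -> list[tuple[str, int, str, str]]:
    model = st[0]
    lig_xyz = []
    for chain in model:
        for res in chain:
            if res.name.strip() == ligand_code:
                lig_xyz.append(_residue_heavy_coords(res))
    if not lig_xyz:
        return []
    lig = np.vstack(lig_xyz)
    out = []
    for chain in model:
        for res in chain:
            link_atom = ANCHOR_ATOM.get(res.name.strip())
            if link_atom is None:
                continue
            for atom in res:
                if atom.name.strip() == link_atom:
                    xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    d = np.sqrt(((lig - xyz) ** 2).sum(-1)).min()
                    if d <= LINK_CUTOFF[link_atom]:
                        out.append((chain.name, res.seqid.num,
                                    res.name.strip(), link_atom))
    return out


def read_complex(path: str | Path, ligand_code: str,
                 buffer_names: Iterable[str] = ()) -> BenchmarkEntry:
    """Read a covalent co-crystal complex from a PDB or mmCIF file.

    Identifies the covalent linkage from LINK/struct_conn records, falling
    back to a bond-length distance rule; strips waters, metals and other het
    groups; retains only the protein chain carrying the linkage.  Alternate
    locations: altloc A kept, occupancy ignored.

    Raises :class:`NotCovalentError` if no linkage to the named ligand is
    found, :class:`UnsupportedAnchorError` if the linked residue is not
    Cys/Ser.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()
    buffer_names = {b.upper() for b in buffer_names}

    model = st[0]
    if not any(res.name.strip() == ligand_code
               for chain in model for res in chain):
        raise ValueError(f"ligand code {ligand_code!r} not found in {path}")

    context = _scan_context(st, ligand_code, buffer_names)

    linkages = _find_linkages_from_connections(st, ligand_code)
    if not linkages:
        linkages = _find_linkages_by_distance(st, ligand_code)
    if not linkages:
        raise NotCovalentError(
            f"not a covalent complex: no linkage between {ligand_code!r} "
            "and an anchor-capable residue"
        )
    context.n_covalent_linkages = len(linkages)

    chain_name, resnum, resname, link_atom = linkages[0]
    if resname not in ANCHOR_ATOM:
        raise UnsupportedAnchorError(
            f"unsupported anchor: linkage to {resname} {resnum} "
            "(only CYS and SER are supported)"
        )
    if link_atom not in ("SG", "OG"):
        link_atom = ANCHOR_ATOM[resname]

    # anchor residue coordinates
    anchor_atoms: dict[str, np.ndarray] = {}
    for chain in model:
        if chain.name != chain_name:
            continue
        for res in chain:
            if res.seqid.num == resnum and res.name.strip() == resname:
                for atom in res:
                    anchor_atoms[atom.name.strip()] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z])
    anchor = AnchorResidue(chain=chain_name, residue_number=resnum,
                           residue_name=resname, link_atom=link_atom,
                           atoms=anchor_atoms)

    # ligand pose (heavy atoms; PDB carries no bonds -> perceived later)
    lig_elements, lig_coords = [], []
    for chain in model:
        for res in chain:
            if res.name.strip() == ligand_code:
                for atom in res:
                    if atom.element.name != "H":
                        lig_elements.append(atom.element.name)
                        lig_coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                break
    reference = LigandPose(elements=tuple(lig_elements),
                           coords=np.array(lig_coords), name=ligand_code)

    # receptor table: the linked chain's polymer residues only
    rows = []
    for chain in model:
        if chain.name != chain_name:
            continue
        for res in chain:
            name = res.name.strip()
            if name == ligand_code or name in _WATER_NAMES or _is_metal(res):
                continue
            info = gemmi.find_tabulated_residue(name)
            if info is None or not info.is_amino_acid():
                continue  # strip cofactors / agents from the retained target
            for atom in res:
                rows.append((chain.name, res.seqid.num, name,
                             atom.name.strip(), atom.element.name,
                             atom.pos.x, atom.pos.y, atom.pos.z))
    receptor = pd.DataFrame(
        rows, columns=["chain", "resnum", "resname", "name", "element",
                       "x", "y", "z"])

    resolution = float(st.resolution) if st.resolution else None
    pre = reference.to_rdkit()

    return BenchmarkEntry(
        entry_id=st.name.lower() if st.name else path.stem,
        anchor=anchor,
        reference_ligand=reference,
        pre_reaction_ligand=pre,
        resolution=resolution,
        context=context,
        receptor_atoms=receptor,
        source_path=str(path),
    )


def write_entry_pdb(entry: BenchmarkEntry, path: str | Path) -> None:
    """Write a stripped entry back to PDB (receptor + ligand + LINK)."""
    st = gemmi.Structure()
    st.name = entry.entry_id
    if entry.resolution:
        st.resolution = entry.resolution
    model = gemmi.Model("1")
    chain = gemmi.Chain(entry.anchor.chain)
    if entry.receptor_atoms is not None:
        for (resnum, resname), grp in entry.receptor_atoms.groupby(
                ["resnum", "resname"], sort=True):
            res = gemmi.Residue()
            res.name = resname
            res.het_flag = "A"
            res.seqid = gemmi.SeqId(int(resnum), " ")
            for _, row in grp.iterrows():
                a = gemmi.Atom()
                a.name = row["name"]
                a.element = gemmi.Element(row["element"])
                a.pos = gemmi.Position(row.x, row.y, row.z)
                res.add_atom(a)
            chain.add_residue(res)
    lig = gemmi.Residue()
    lig.name = entry.reference_ligand.name or "LIG"
    lig.seqid = gemmi.SeqId(900, " ")
    lig.het_flag = "H"
    counts: dict[str, int] = {}
    lig_atom_names = []
    for e, xyz in zip(entry.reference_ligand.elements,
                      entry.reference_ligand.coords):
        counts[e] = counts.get(e, 0) + 1
        a = gemmi.Atom()
        a.name = f"{e.upper()}{counts[e]}"
        lig_atom_names.append(a.name)
        a.element = gemmi.Element(e)
        a.pos = gemmi.Position(*map(float, xyz))
        lig.add_atom(a)
    chain.add_residue(lig)
    model.add_chain(chain)
    st.add_model(model)

    # LINK record: anchor link atom <-> nearest ligand heavy atom
    link_xyz = entry.anchor.link_coord
    d = np.sqrt(((entry.reference_ligand.coords - link_xyz) ** 2).sum(-1))
    nearest = int(np.argmin(d))
    con = gemmi.Connection()
    con.name = "covale1"
    con.type = gemmi.ConnectionType.Covale
    p1 = gemmi.AtomAddress()
    p1.chain_name = entry.anchor.chain
    p1.res_id = gemmi.ResidueId()
    p1.res_id.name = entry.anchor.residue_name
    p1.res_id.seqid = gemmi.SeqId(entry.anchor.residue_number, " ")
    p1.atom_name = entry.anchor.link_atom
    p2 = gemmi.AtomAddress()
    p2.chain_name = entry.anchor.chain
    p2.res_id = gemmi.ResidueId()
    p2.res_id.name = lig.name
    p2.res_id.seqid = gemmi.SeqId(900, " ")
    p2.atom_name = lig_atom_names[nearest]
    con.partner1, con.partner2 = p1, p2
    st.connections.append(con)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# pose files

_SCORE_PROPERTY_NAMES = ("score", "Score", "SCORE", "docking_score",
                         "minimizedAffinity", "r_i_docking_score")


def read_pose_file(path: str | Path,
                   score_property: str | None = None,
                   score_orientation: str = "lower_better") -> list[LigandPose]:
    """Read an SDF/MOL/MOL2 pose file; records keep file order as rank.

    The score is read from ``score_property`` if given, otherwise from the
    first conventional score field present on each record.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    poses: list[LigandPose] = []
    try:
        if suffix == ".mol2":
            mols = [Chem.MolFromMol2File(str(path), removeHs=False,
                                         sanitize=False)]
        else:
            supplier = Chem.SDMolSupplier(str(path), removeHs=False,
                                          sanitize=False)
            mols = list(supplier)
    except OSError as exc:
        raise ValueError(f"cannot parse pose file {path}: {exc}") from exc
    for i, mol in enumerate(mols):
        if mol is None:
            raise ValueError(f"unparsable record {i + 1} in {path}")
        mol.UpdatePropertyCache(strict=False)
        score = None
        names = ((score_property,) if score_property
                 else _SCORE_PROPERTY_NAMES)
        for nm in names:
            if nm and mol.HasProp(nm):
                score = float(mol.GetProp(nm))
                break
        props = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        poses.append(LigandPose.from_rdkit(
            mol, pose_rank=i + 1, score=score,
            score_orientation=score_orientation,
            name=mol.GetProp("_Name") if mol.HasProp("_Name") else "",
            properties=props))
    if not poses:
        raise ValueError(f"no records in {path}")
    return poses


def write_pose_file(poses: Sequence[LigandPose], path: str | Path) -> None:
    """Write poses to a multi-record SDF preserving order and scores."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for pose in poses:
            mol = pose.to_rdkit()
            if pose.name:
                mol.SetProp("_Name", pose.name)
            if pose.score is not None:
                mol.SetProp("score", repr(float(pose.score)))
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# tabular results

def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a results table to CSV or JSON (by extension), losslessly."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(table.to_dict(orient="records"),
                                   indent=2, default=float) + "\n")
    else:
        table.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a benchmark metadata CSV (entry_id, receptor_type, ...)."""
    meta = pd.read_csv(path)
    if "entry_id" not in meta.columns:
        raise ValueError("metadata CSV must have an entry_id column")
    return meta
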