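"""Synthetic benchmarks with analytically known answers.

Fabricates complete toy covalent-docking benchmarks — receptor stubs,
covalent ligands for every warhead class, and mock docking runs — so the
whole evaluation pipeline is testable without external data or a docking
engine.

The key construction: mock poses are *pure rigid translations* of the
reference ligand.  The no-fit RMSD of a uniform translation equals the
translation norm exactly, and minimizing over graph automorphisms cannot
reduce it (for any permutation P of identical coordinates,
mean ||x_P(i) + t - x_i||^2 = ||t||^2 + mean ||x_P(i) - x_i||^2 >= ||t||^2),
so planted per-pose RMSDs are recovered to machine precision regardless of
the symmetry setting.  Rotational/jitter perturbations are available as an
opt-in stress mode, where recovery is only approximate.

Scores are generated rank-consistent with a controllable score-RMSD
correlation rho: at rho = 1 the best-scored pose is the best-sampled pose;
lower rho creates the realistic regime where scoring picks a worse pose
than the sampler found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from covbench.datamodel import (
    AnchorResidue,
    BenchmarkEntry,
    DockingRun,
    LigandPose,
    StructureContext,
    write_entry_pdb,
    write_pose_file,
)
from covbench.warhead import WarheadTaxonomy, classify, default_taxonomy

__all__ = [
    "SyntheticSpec",
    "make_entry",
    "make_run",
    "make_benchmark",
    "RECEPTOR_TYPES",
]

LINK_BOND_LENGTH = {"SG": 1.81, "OG": 1.43}   # A, S-C and O-C single bonds

RECEPTOR_TYPES = (
    "Hydrolase", "Transferase", "Ligase", "Lyase", "Oxidoreductase",
    "Isomerase", "Transcription", "Viral Protein", "Metal binding protein",
)

# Idealized residue templates (A).  Backbone geometry is standard
# (N-CA 1.46, CA-C 1.52); side chains carry the anchor atom at a covalent
# CB-SG / CB-OG distance.
_RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [
        ("N", "N", (0.00, 0.00, 0.00)),
        ("CA", "C", (1.46, 0.00, 0.00)),
        ("C", "C", (2.00, 1.42, 0.00)),
        ("O", "O", (1.25, 2.39, 0.00)),
    ],
    "CYS": [
        ("N", "N", (0.00, 0.00, 0.00)),
        ("CA", "C", (1.46, 0.00, 0.00)),
        ("C", "C", (2.00, 1.42, 0.00)),
        ("O", "O", (1.25, 2.39, 0.00)),
        ("CB", "C", (2.00, -0.77, 1.21)),
        ("SG", "S", (3.80, -0.90, 1.25)),
    ],
    "SER": [
        ("N", "N", (0.00, 0.00, 0.00)),
        ("CA", "C", (1.46, 0.00, 0.00)),
        ("C", "C", (2.00, 1.42, 0.00)),
        ("O", "O", (1.25, 2.39, 0.00)),
        ("CB", "C", (2.00, -0.77, 1.21)),
        ("OG", "O", (3.40, -0.87, 1.24)),
    ],
}
_PEPTIDE_STEP = np.array([3.8, 0.0, 0.0])   # CA-CA spacing along the chain


def _receptor_frame(anchor_name: str, chain: str = "A",
                    anchor_resnum: int = 25) -> pd.DataFrame:
    """A Gly-X-Gly receptor stub with the anchor residue in the middle."""
    rows = []
    for offset, resname in ((-1, "GLY"), (0, anchor_name), (1, "GLY")):
        shift = offset * _PEPTIDE_STEP
        for name, element, xyz in _RESIDUE_TEMPLATES[resname]:
            x, y, z = np.asarray(xyz) + shift
            rows.append((chain, anchor_resnum + offset, resname, name,
                         element, x, y, z))
    return pd.DataFrame(rows, columns=["chain", "resnum", "resname", "name",
                                       "element", "x", "y", "z"])


def _embed_example(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1) or 1
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles!r}")
    return Chem.RemoveHs(mol)


def make_entry(warhead_class: str,
               anchor: str | None = None,
               seed: int = 0,
               entry_id: str | None = None,
               resolution: float = 1.8,
               receptor_type: str = "Hydrolase",
               uniprot_id: str = "P00000",
               kinase_domain: str | None = None,
               taxonomy: WarheadTaxonomy | None = None,
               out_dir: str | Path | None = None) -> BenchmarkEntry:
    """Fabricate one benchmark entry for a warhead class.

    The class's example chemotype is embedded in 3D (seeded, deterministic)
    and placed so its electrophilic link atom sits one covalent bond length
    from the anchor side-chain atom.  With ``out_dir`` the receptor PDB
    (LINK record included) and ligand SDF are written to disk.
    """
    taxonomy = taxonomy or default_taxonomy()
    rule = taxonomy.rule(warhead_class)
    anchor_name = (anchor or rule.anchor).upper()
    entry_id = entry_id or f"syn{abs(hash((warhead_class, seed))) % 10**4:04d}"

    mol = _embed_example(rule.example, seed)
    result = classify(mol, anchor_name, taxonomy)
    if result.warhead_class != warhead_class:
        raise ValueError(
            f"example for {warhead_class!r} classified as "
            f"{result.warhead_class!r}")

    receptor = _receptor_frame(anchor_name)
    anchor_atoms = {
        row["name"]: np.array([row.x, row.y, row.z])
        for _, row in receptor[receptor.resname == anchor_name].iterrows()
    }
    link_atom = "SG" if anchor_name == "CYS" else "OG"
    anchor_res = AnchorResidue(chain="A", residue_number=25,
                               residue_name=anchor_name, link_atom=link_atom,
                               atoms=anchor_atoms)

    # place the ligand: link atom one bond length beyond the anchor atom,
    # pointing away from the receptor backbone
    conf = mol.GetConformer()
    xyz = np.array([list(conf.GetAtomPosition(i))
                    for i in range(mol.GetNumAtoms())])
    direction = np.array([1.0, -0.1, 0.3])
    direction /= np.linalg.norm(direction)
    target = anchor_res.link_coord + LINK_BOND_LENGTH[link_atom] * direction
    shift = target - xyz[result.link_atom_index]
    xyz = xyz + shift
    for i, p in enumerate(xyz):
        conf.SetAtomPosition(i, tuple(map(float, p)))

    reference = LigandPose.from_rdkit(mol, name="LIG")
    entry = BenchmarkEntry(
        entry_id=entry_id,
        anchor=anchor_res,
        reference_ligand=reference,
        pre_reaction_ligand=mol,
        receptor_type=receptor_type,
        uniprot_id=uniprot_id,
        warhead_class=warhead_class,
        reaction_class=rule.reaction_class,
        resolution=resolution,
        kinase_domain=kinase_domain,
        context=StructureContext(),
        receptor_atoms=receptor,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_entry_pdb(entry, out_dir / f"{entry_id}.pdb")
        write_pose_file([reference], out_dir / f"{entry_id}_ligand.sdf")
    return entry


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_run(entry: BenchmarkEntry,
             target_s1: float | None = None,
             target_s2: float | None = None,
             target_smax: float | None = None,
             n_poses: int = 10,
             seed: int = 0,
             tool_id: str = "mock",
             pose_rmsds: Sequence[float] | None = None,
             jitter: float = 0.0,
             score_orientation: str = "lower_better") -> DockingRun:
    """Build a mock docking run with planted per-pose RMSDs.

    Either pass explicit ``pose_rmsds`` (rank order) or targets
    (S1, S2, Smax) with 0 <= S2 <= S1 <= Smax; intermediate poses are
    spread uniformly between S2 and Smax.  Poses are translations of the
    reference along random directions, so the planted values are exact;
    ``jitter`` adds per-atom noise for stress tests (recovery then only
    approximate).
    """
    rng = np.random.default_rng(seed)
    if pose_rmsds is None:
        if target_s1 is None or target_s2 is None or target_smax is None:
            raise ValueError("provide pose_rmsds or all three targets")
        if not (0.0 <= target_s2 <= target_s1 <= target_smax):
            raise ValueError(
                "infeasible targets: need 0 <= S2 <= S1 <= Smax")
        if n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        rmsds = [float(target_s1)]
        if n_poses >= 2:
            rmsds.append(float(target_s2))
        if n_poses >= 3:
            rmsds.append(float(target_smax))
        extra = n_poses - len(rmsds)
        if extra > 0:
            rmsds.extend(rng.uniform(target_s2, target_smax,
                                     size=extra).tolist())
    else:
        rmsds = [float(r) for r in pose_rmsds]
        if min(rmsds) < 0:
            raise ValueError("pose RMSDs must be non-negative")

    ref = entry.reference_ligand
    dirs = _unit_vectors(rng, len(rmsds))
    poses = []
    best = min(rmsds)
    worst = max(rmsds)
    for rank, (r, d) in enumerate(zip(rmsds, dirs), start=1):
        coords = ref.coords + r * d
        if jitter > 0:
            coords = coords + rng.normal(scale=jitter, size=coords.shape)
        span = (worst - best) or 1.0
        score = (rank + (r - best) / span) \
            if score_orientation == "lower_better" else -(rank + (r - best) / span)
        poses.append(LigandPose(
            elements=ref.elements, coords=coords, bonds=ref.bonds,
            pose_rank=rank, score=float(score),
            score_orientation=score_orientation, name=ref.name))
    return DockingRun(tool_id=tool_id, entry_id=entry.entry_id, poses=poses)


@dataclass
class SyntheticSpec:
    """Recipe for a full synthetic benchmark.

    ``tool_profiles`` maps (tool_id, warhead_class) or tool_id to a
    (mu, sigma) pair: per-pose RMSDs are drawn |N(mu, sigma)|.
    ``score_rmsd_rho`` controls how faithfully each tool's score ranks its
    poses by true RMSD (1 = scoring always finds the sampler's best pose).
    """

    n_entries: int = 30
    warhead_mix: Mapping[str, float] | None = None
    tool_profiles: Mapping = field(
        default_factory=lambda: {"toolA": (1.5, 0.5), "toolB": (2.5, 0.8)})
    poses_per_run: int = 10
    score_rmsd_rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poses_per_run < 1:
            raise ValueError("poses_per_run must be >= 1")
        if self.warhead_mix is not None:
            total = sum(self.warhead_mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError("warhead mix proportions must sum to 1")

    def profile_for(self, tool_id: str, warhead_class: str
                    ) -> tuple[float, float]:
        prof = self.tool_profiles
        if (tool_id, warhead_class) in prof:
            return prof[(tool_id, warhead_class)]
        return prof[tool_id]

    @property
    def tools(self) -> list[str]:
        names = []
        for key in self.tool_profiles:
            t = key[0] if isinstance(key, tuple) else key
            if t not in names:
                names.append(t)
        return names


def make_benchmark(spec: SyntheticSpec, out_dir: str | Path | None = None
                   ) -> tuple[list[BenchmarkEntry],
                              list[DockingRun],
                              pd.DataFrame,
                              pd.DataFrame]:
    """Generate entries, per-tool mock runs, metadata and ground truth.

    Returns (entries, runs, metadata, ground_truth); the ground-truth table
    lists the planted S1/S2/Smax for every (tool, entry), which downstream
    evaluation must reproduce exactly (translation-only construction).
    """
    taxonomy = default_taxonomy()
    rng = np.random.default_rng(spec.seed)
    mix = spec.warhead_mix or {
        r.warhead_class: r.frequency / 330.0 for r in taxonomy.rules}
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    draws = rng.choice(len(classes), size=spec.n_entries, p=probs)

    entries, runs, truth_rows, meta_rows = [], [], [], []
    for k, ci in enumerate(draws):
        wclass = classes[ci]
        entry = make_entry(
            wclass,
            seed=int(rng.integers(2 ** 31 - 1)),
            entry_id=f"syn{k:04d}",
            receptor_type=RECEPTOR_TYPES[k % len(RECEPTOR_TYPES)],
            uniprot_id=f"P{k % 7:05d}",
            taxonomy=taxonomy,
            out_dir=Path(out_dir) / "entries" if out_dir else None,
        )
        entries.append(entry)
        meta_rows.append({
            "entry_id": entry.entry_id,
            "receptor_type": entry.receptor_type,
            "uniprot_id": entry.uniprot_id,
            "warhead_class": entry.warhead_class,
            "reaction_class": entry.reaction_class,
            "kinase_domain": entry.kinase_domain,
        })
        for tool in spec.tools:
            mu, sigma = spec.profile_for(tool, wclass)
            rmsds = np.abs(rng.normal(mu, sigma, size=spec.poses_per_run))
            # rank poses by a score correlated with true RMSD
            rho = spec.score_rmsd_rho
            noise = rng.normal(size=spec.poses_per_run)
            z = (rmsds - rmsds.mean()) / (rmsds.std() or 1.0)
            pseudo_score = rho * z + math.sqrt(max(0.0, 1 - rho ** 2)) * noise
            order = np.argsort(pseudo_score)      # best score first
            ranked = rmsds[order]
            run = make_run(entry, pose_rmsds=ranked.tolist(),
                           seed=int(rng.integers(2 ** 31 - 1)),
                           tool_id=tool)
            runs.append(run)
            truth_rows.append({
                "tool_id": tool, "entry_id": entry.entry_id,
                "warhead_class": wclass,
                "s1": float(ranked[0]),
                "s2": float(ranked.min()),
                "smax": float(ranked.max()),
            })
            if out_dir is not None:
                run_dir = Path(out_dir) / "runs" / tool
                run_dir.mkdir(parents=True, exist_ok=True)
                write_pose_file(run.poses, run_dir / f"{entry.entry_id}.sdf")

    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metadata.to_csv(out / "metadata.csv", index=False)
        truth.to_csv(out / "ground_truth.csv", index=False)
    return entries, runs, metadata, truth
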