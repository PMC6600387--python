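"""Pose accuracy: symmetry-aware heavy-atom RMSD and per-complex metrics.

Docking accuracy is positional in the receptor frame, so RMSD here is
*no-fit* (in-place): no superposition is performed.  Topologically
equivalent atoms (e.g. the two ortho carbons of a para-substituted ring)
are handled by minimizing over graph automorphisms of the ligand, since
pose files from different engines renumber atoms and a symmetric flip is
not a docking error.

Per-complex measurements follow the standard success/failure bookkeeping
for covalent re-docking: S1 is the RMSD of the top-scored pose ("Best
Scored Pose"), S2 the minimum over all retained poses ("Best Sampled
Pose"), Smax the maximum ("maximal deviated pose").  A run is a *success*
when S1 <= tau and a *failure* when both S1 > tau and S2 > tau (the two
flags are deliberately non-complementary: a run whose top pose misses but
whose sampler found a near-native pose is neither).  The near-native
threshold tau defaults to 2.0 A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from covbench.datamodel import BenchmarkEntry, DockingRun, LigandPose

__all__ = [
    "ComplexResult",
    "AtomCorrespondenceError",
    "ligand_rmsd",
    "pose_rmsds",
    "evaluate_run",
    "AUTOMORPHISM_CAP",
]

#: Beyond this many atom mappings the search falls back to the canonical
#: correspondence (with a warning) rather than enumerating automorphisms.
AUTOMORPHISM_CAP = 10_000

DEFAULT_TAU = 2.0


class AtomCorrespondenceError(ValueError):
    """Pose and reference do not share a heavy-atom molecular graph."""


@dataclass(frozen=True)
class ComplexResult:
    """Per-(tool, entry) pose-accuracy measurements (all RMSDs in A)."""

    tool_id: str
    entry_id: str
    s1: float          # Best Scored Pose RMSD
    s2: float          # Best Sampled Pose RMSD
    smax: float        # maximal deviated pose RMSD
    tau: float = DEFAULT_TAU
    n_poses: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.s2 <= self.s1 + 1e-9 <= self.smax + 2e-9):
            raise ValueError(
                f"inconsistent measurements: need 0 <= S2 <= S1 <= Smax, "
                f"got S1={self.s1}, S2={self.s2}, Smax={self.smax}")

    @property
    def p_deviation(self) -> float:
        """S1 - S2: the gap between scoring and sampling accuracy."""
        return self.s1 - self.s2

    @property
    def success(self) -> bool:
        return self.s1 <= self.tau

    @property
    def failure(self) -> bool:
        return self.s1 > self.tau and self.s2 > self.tau


def _heavy_mol(pose: LigandPose) -> tuple[Chem.Mol, np.ndarray]:
    """Heavy-atom RDKit graph plus matching coordinate rows."""
    idx = pose.heavy_indices
    sub = LigandPose(
        elements=tuple(pose.elements[i] for i in idx),
        coords=pose.coords[idx],
        bonds=tuple(
            (int(np.searchsorted(idx, i)), int(np.searchsorted(idx, j)), o)
            for i, j, o in pose.bonds
            if i in set(idx.tolist()) and j in set(idx.tolist())),
        pose_rank=pose.pose_rank,
    )
    return sub.to_rdkit(), sub.coords


def _mappings(ref_mol: Chem.Mol, pose_mol: Chem.Mol,
              symmetry: bool) -> list[tuple[int, ...]]:
    """Isomorphisms pose->ref: mapping m with m[i] = pose atom for ref atom i.

    With ``symmetry`` all graph isomorphisms (capped) are returned; without,
    a single canonical correspondence built from canonical atom ranks.
    """
    if symmetry:
        matches = pose_mol.GetSubstructMatches(
            ref_mol, uniquify=False, useChirality=False,
            maxMatches=AUTOMORPHISM_CAP + 1)
        if matches and len(matches) <= AUTOMORPHISM_CAP:
            return list(matches)
        if len(matches) > AUTOMORPHISM_CAP:
            warnings.warn(
                f"automorphism count exceeds cap ({AUTOMORPHISM_CAP}); "
                "falling back to the canonical atom correspondence")
    # canonical correspondence: pair atoms by canonical rank
    ranks_ref = list(Chem.CanonicalRankAtoms(ref_mol, breakTies=True))
    ranks_pose = list(Chem.CanonicalRankAtoms(pose_mol, breakTies=True))
    by_rank_pose = {r: i for i, r in enumerate(ranks_pose)}
    try:
        mapping = tuple(by_rank_pose[r] for r in ranks_ref)
    except KeyError as exc:
        raise AtomCorrespondenceError(
            "atom correspondence failure: canonical ranks do not align"
        ) from exc
    return [mapping]


def ligand_rmsd(pose: LigandPose, reference: LigandPose,
                symmetry: bool = True) -> float:
    """No-fit heavy-atom RMSD between a docked pose and the reference.

    Both poses must live in the same (receptor) coordinate frame and share
    a heavy-atom molecular graph; atom order may differ.  With
    ``symmetry=True`` the RMSD is minimized over graph automorphisms.
    """
    if pose.heavy_composition() != reference.heavy_composition():
        raise AtomCorrespondenceError(
            "atom correspondence failure: heavy-atom compositions differ "
            f"({pose.heavy_composition()} vs {reference.heavy_composition()})")
    ref_mol, ref_xyz = _heavy_mol(reference)
    pose_mol, pose_xyz = _heavy_mol(pose)

    if pose_mol.GetNumBonds() == 0 and ref_mol.GetNumBonds() == 0:
        # bond-free point sets: match by element, identity order within element
        mappings = [_element_order_mapping(reference, pose)]
    else:
        if not pose_mol.GetSubstructMatch(ref_mol):
            # references extracted from PDB het records carry no bond
            # orders; retry on the order-collapsed skeleton
            ref_mol = _collapse_bond_orders(ref_mol)
            pose_mol = _collapse_bond_orders(pose_mol)
        if not pose_mol.GetSubstructMatch(ref_mol):
            raise AtomCorrespondenceError(
                "atom correspondence failure: heavy-atom graphs are not "
                "isomorphic")
        mappings = _mappings(ref_mol, pose_mol, symmetry)

    best = np.inf
    for m in mappings:
        diff = pose_xyz[list(m)] - ref_xyz
        rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
        best = min(best, rmsd)
    return best


def _collapse_bond_orders(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.RWMol(mol)
    for bond in out.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    for atom in out.GetAtoms():
        atom.SetIsAromatic(False)
        atom.SetNoImplicit(True)
    result = out.GetMol()
    result.UpdatePropertyCache(strict=False)
    return result


def _element_order_mapping(reference: LigandPose,
                           pose: LigandPose) -> tuple[int, ...]:
    ridx, pidx = reference.heavy_indices, pose.heavy_indices
    relems = [reference.elements[i].capitalize() for i in ridx]
    pelems = [pose.elements[i].capitalize() for i in pidx]
    pools: dict[str, list[int]] = {}
    for local, e in enumerate(pelems):
        pools.setdefault(e, []).append(local)
    try:
        return tuple(pools[e].pop(0) for e in relems)
    except (KeyError, IndexError) as exc:
        raise AtomCorrespondenceError(
            "atom correspondence failure: element multisets differ") from exc


def pose_rmsds(run: DockingRun, reference: LigandPose,
               symmetry: bool = True) -> np.ndarray:
    """RMSD of every pose in rank order."""
    return np.array([ligand_rmsd(p, reference, symmetry=symmetry)
                     for p in run.poses])


def evaluate_run(run: DockingRun, entry: BenchmarkEntry,
                 tau: float = DEFAULT_TAU,
                 symmetry: bool = True) -> ComplexResult:
    """Reduce a docking run to its per-complex measurements.

    S1 = RMSD of the rank-1 pose, S2 = min over all poses, Smax = max over
    all poses; success/failure flags use the near-native threshold ``tau``
    (success at S1 == tau inclusive).
    """
    rmsds = pose_rmsds(run, entry.reference_ligand, symmetry=symmetry)
    return ComplexResult(
        tool_id=run.tool_id,
        entry_id=run.entry_id,
        s1=float(rmsds[0]),
        s2=float(rmsds.min()),
        smax=float(rmsds.max()),
        tau=tau,
        n_poses=len(rmsds),
    )
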