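"""Benchmark curation: the filter pipeline that builds a covalent-docking
benchmark from candidate co-crystal complexes.

Candidates pass through an ordered, auditable sequence of filters:

1. resolution strictly below a cutoff (default 3.0 A);
2. structural context — no nucleic-acid chains, no cofactor heavy atom
   within 8 A of the ligand (scanned on the structure as deposited,
   *before* stripping, else the rule could never fire);
3. anchor — the covalent linkage must be a single bond to a Cys-SG or
   Ser-OG;
4. ligand size — at least 5 heavy atoms and strictly fewer than 30
   rotatable bonds, counted on the pre-reaction ligand (the species that
   is actually docked).

Every exclusion is attributed to the first filter that fired, so the
report is an audit trail; the retained *set* is order-insensitive.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
import yaml
from rdkit import Chem

from covbench.datamodel import ANCHOR_ATOM, BenchmarkEntry

__all__ = [
    "CurationReport",
    "filter_resolution",
    "filter_ligand_size",
    "filter_anchor",
    "filter_context",
    "run_curation",
    "count_rotatable_bonds",
    "default_buffer_names",
]

RESOLUTION_CUTOFF = 3.0      # A, strict
MIN_HEAVY_ATOMS = 5
MAX_ROTATABLE_BONDS = 30     # strict upper bound
COFACTOR_RADIUS = 8.0        # A


def default_buffer_names() -> set[str]:
    """Het-group codes treated as buffer/crystallization agents, not
    cofactors, in the proximity rule.  Ships as editable config."""
    ref = importlib.resources.files("covbench") / "data" / "buffers.yaml"
    with importlib.resources.as_file(ref) as path:
        data = yaml.safe_load(Path(path).read_text())
    return {str(x).upper() for x in data["buffer_names"]}


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Strict rotatable-bond count.

    A bond rotates when it is a single, acyclic bond between two heavy
    atoms that each carry at least one further heavy neighbor; amide C-N
    bonds are excluded.  This is the common strict convention; the exact
    dictionary is a declared choice.
    """
    m = Chem.Mol(mol)
    m.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(m)
    n = 0
    for bond in m.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        da = sum(1 for x in a.GetNeighbors()
                 if x.GetAtomicNum() > 1 and x.GetIdx() != b.GetIdx())
        db = sum(1 for x in b.GetNeighbors()
                 if x.GetAtomicNum() > 1 and x.GetIdx() != a.GetIdx())
        if da < 1 or db < 1:
            continue
        if _is_amide_cn(a, b) or _is_amide_cn(b, a):
            continue
        n += 1
    return n


def _is_amide_cn(c: Chem.Atom, n: Chem.Atom) -> bool:
    if c.GetAtomicNum() != 6 or n.GetAtomicNum() != 7:
        return False
    return any(
        b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetOtherAtom(c).GetAtomicNum() == 8
        for b in c.GetBonds())


# --- individual filters -----------------------------------------------------
# Each filter returns (kept_entries, reasons) where reasons maps the
# excluded entry_id to a human-readable cause.

FilterResult = tuple[list[BenchmarkEntry], dict[str, str]]


def filter_resolution(entries: Iterable[BenchmarkEntry],
                      cutoff: float = RESOLUTION_CUTOFF) -> FilterResult:
    """Retain complexes with resolution strictly below ``cutoff``."""
    kept, reasons = [], {}
    for e in entries:
        if e.resolution is None:
            reasons[e.entry_id] = "no resolution"
        elif e.resolution < cutoff:
            kept.append(e)
        else:
            reasons[e.entry_id] = (
                f"resolution {e.resolution:g} A >= {cutoff:g} A")
    return kept, reasons


def filter_ligand_size(entries: Iterable[BenchmarkEntry],
                       min_heavy: int = MIN_HEAVY_ATOMS,
                       max_rotatable: int = MAX_ROTATABLE_BONDS
                       ) -> FilterResult:
    """Retain ligands with >= ``min_heavy`` heavy atoms and strictly fewer
    than ``max_rotatable`` rotatable bonds (on the pre-reaction ligand)."""
    kept, reasons = [], {}
    for e in entries:
        mol = e.pre_reaction_ligand
        if mol is None or mol.GetNumAtoms() == 0:
            reasons[e.entry_id] = "empty ligand"
            continue
        n_heavy = mol.GetNumHeavyAtoms()
        if n_heavy < min_heavy:
            reasons[e.entry_id] = (
                f"{n_heavy} heavy atoms < {min_heavy}")
            continue
        n_rot = count_rotatable_bonds(mol)
        if n_rot >= max_rotatable:
            reasons[e.entry_id] = (
                f"{n_rot} rotatable bonds >= {max_rotatable}")
            continue
        kept.append(e)
    return kept, reasons


def filter_anchor(entries: Iterable[BenchmarkEntry]) -> FilterResult:
    """Retain entries covalently bound to CYS-SG or SER-OG through exactly
    one single bond."""
    kept, reasons = [], {}
    for e in entries:
        name = e.anchor.residue_name
        if name not in ANCHOR_ATOM or e.anchor.link_atom != ANCHOR_ATOM[name]:
            reasons[e.entry_id] = f"anchor {name}-{e.anchor.link_atom} " \
                                  "is not CYS-SG or SER-OG"
        elif e.context.n_covalent_linkages != 1:
            reasons[e.entry_id] = (
                f"{e.context.n_covalent_linkages} covalent linkages "
                "(exactly one single bond required)")
        else:
            kept.append(e)
    return kept, reasons


def filter_context(entries: Iterable[BenchmarkEntry],
                   cofactor_radius: float = COFACTOR_RADIUS) -> FilterResult:
    """Exclude complexes with nucleic-acid chains or a cofactor heavy atom
    within ``cofactor_radius`` of any ligand heavy atom (as deposited)."""
    kept, reasons = [], {}
    for e in entries:
        if e.context.has_nucleic_chains:
            reasons[e.entry_id] = "nucleic-acid chain present"
        elif e.context.cofactor_min_distance < cofactor_radius:
            reasons[e.entry_id] = (
                f"cofactor at {e.context.cofactor_min_distance:.2f} A "
                f"< {cofactor_radius:g} A from ligand")
        else:
            kept.append(e)
    return kept, reasons


# --- pipeline ---------------------------------------------------------------


@dataclass
class CurationReport:
    """Outcome of the full filter pipeline."""

    retained: list[BenchmarkEntry]
    table: pd.DataFrame                    # entry_id, per-filter flag, reason
    stage_counts: list[tuple[str, int]]    # count surviving after each stage

    @property
    def retained_ids(self) -> list[str]:
        return [e.entry_id for e in self.retained]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts, columns=["stage", "retained"])


def run_curation(entries: Sequence[BenchmarkEntry],
                 resolution_cutoff: float = RESOLUTION_CUTOFF,
                 min_heavy: int = MIN_HEAVY_ATOMS,
                 max_rotatable: int = MAX_ROTATABLE_BONDS,
                 cofactor_radius: float = COFACTOR_RADIUS) -> CurationReport:
    """Apply the filters in order, attributing each exclusion to the first
    filter that fired."""
    entries = list(entries)
    stages: list[tuple[str, Callable[[list[BenchmarkEntry]], FilterResult]]] = [
        ("resolution",
         lambda es: filter_resolution(es, resolution_cutoff)),
        ("context",
         lambda es: filter_context(es, cofactor_radius)),
        ("anchor", filter_anchor),
        ("ligand_size",
         lambda es: filter_ligand_size(es, min_heavy, max_rotatable)),
    ]
    flags: dict[str, dict[str, bool]] = {e.entry_id: {} for e in entries}
    reason: dict[str, str] = {}
    excluded_by: dict[str, str] = {}

    current = entries
    stage_counts = [("input", len(entries))]
    for name, fn in stages:
        kept, reasons = fn(current)
        for e in current:
            flags[e.entry_id][name] = e.entry_id not in reasons
        for eid, why in reasons.items():
            reason[eid] = why
            excluded_by[eid] = name
        current = kept
        stage_counts.append((name, len(current)))

    rows = []
    for e in entries:
        row = {"entry_id": e.entry_id}
        for name, _ in stages:
            row[f"pass_{name}"] = flags[e.entry_id].get(name)
        row["retained"] = e.entry_id not in excluded_by
        row["excluded_by"] = excluded_by.get(e.entry_id, "")
        row["reason"] = reason.get(e.entry_id, "")
        rows.append(row)
    table = pd.DataFrame(rows)
    return CurationReport(retained=current, table=table,
                          stage_counts=stage_counts)
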