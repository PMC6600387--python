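"""Warhead classification and covalent-reaction templates.

A covalent ligand carries a *warhead*: the electrophilic group that attacks
the nucleophilic anchor residue (Cys thiol or Ser hydroxyl).  Warheads fall
into 15 classes grouped under four reaction classes (nucleophilic addition,
nucleophilic substitution, ring opening, disulfide formation).  The class
definitions live in a versioned SMARTS library (``data/taxonomy.yaml``);
classification is purely structural — no reactivity or energetics is
modelled.

Reaction templates interconvert the pre-reaction ligand (the species a
docking engine samples) and the post-reaction covalent adduct.  Templates
are heavy-atom conserving on both sides (leaving groups are kept as product
fragments), so every template has a well-defined reverse and round-trips
are graph-isomorphic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "WarheadRule",
    "WarheadTaxonomy",
    "ClassificationResult",
    "AdductResult",
    "TemplateError",
    "classify",
    "apply_reaction",
    "reverse_reaction_smarts",
    "load_reaction",
    "tabulate_frequencies",
]

UNCLASSIFIED = "Unclassified"


class TemplateError(ValueError):
    """A reaction template does not apply, or applies ambiguously."""


@dataclass(frozen=True)
class CorePattern:
    smarts: str
    link_atom_pos: int = 0

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ValueError(f"invalid SMARTS {self.smarts!r}")
        return q


@dataclass(frozen=True)
class WarheadRule:
    warhead_class: str
    anchor: str                      # CYS | SER
    reaction_class: str
    reaction_type: str
    priority: int
    core_patterns: tuple[CorePattern, ...]
    example: str = ""
    reaction_smarts: str = ""
    frequencies: tuple[int, ...] = ()

    @property
    def frequency(self) -> int:
        """Observed benchmark count, summed over core variants."""
        return int(sum(self.frequencies))


@dataclass(frozen=True)
class ClassificationResult:
    warhead_class: str
    reaction_class: str | None
    reaction_type: str | None = None
    matched_atoms: frozenset[int] = frozenset()
    link_atom_index: int | None = None

    @property
    def classified(self) -> bool:
        return self.warhead_class != UNCLASSIFIED


@dataclass
class AdductResult:
    """Outcome of applying a covalent-reaction template."""

    adduct: Chem.Mol
    leaving_groups: tuple[Chem.Mol, ...] = ()

    @property
    def products(self) -> tuple[Chem.Mol, ...]:
        return (self.adduct, *self.leaving_groups)


class WarheadTaxonomy:
    """Ordered rule set mapping ligand substructures to warhead classes."""

    def __init__(self, rules: Sequence[WarheadRule],
                 anchor_nucleophile: dict[str, str] | None = None):
        self.rules = tuple(sorted(rules, key=lambda r: -r.priority))
        self.anchor_nucleophile = dict(anchor_nucleophile or
                                       {"CYS": "CS", "SER": "CO"})
        self._validate()

    def _validate(self) -> None:
        seen_pairs, seen_priorities = set(), set()
        for rule in self.rules:
            if not rule.core_patterns:
                raise ValueError(
                    f"{rule.warhead_class}: every class needs >=1 core pattern")
            key = (rule.warhead_class, rule.anchor)
            if key in seen_pairs:
                raise ValueError(f"duplicate (class, anchor) pair {key}")
            seen_pairs.add(key)
            if rule.priority in seen_priorities:
                raise ValueError(
                    f"priority {rule.priority} reused; priorities must form "
                    "a total order")
            seen_priorities.add(rule.priority)
            for p in rule.core_patterns:
                p.query()  # fail fast on bad SMARTS

    @classmethod
    def from_file(cls, path: str | Path) -> "WarheadTaxonomy":
        data = yaml.safe_load(Path(path).read_text())
        rules = [
            WarheadRule(
                warhead_class=c["warhead_class"],
                anchor=c["anchor"].upper(),
                reaction_class=c["reaction_class"],
                reaction_type=c.get("reaction_type", c["reaction_class"]),
                priority=int(c["priority"]),
                core_patterns=tuple(
                    CorePattern(p["smarts"], int(p.get("link_atom_pos", 0)))
                    for p in c["core_patterns"]),
                example=c.get("example", ""),
                reaction_smarts=c.get("reaction_smarts", ""),
                frequencies=tuple(int(f) for f in c.get("frequencies", ())),
            )
            for c in data["classes"]
        ]
        return cls(rules, data.get("anchor_nucleophile"))

    @classmethod
    def default(cls) -> "WarheadTaxonomy":
        ref = importlib.resources.files("covbench") / "data" / "taxonomy.yaml"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)

    def rules_for_anchor(self, anchor: str) -> tuple[WarheadRule, ...]:
        anchor = anchor.upper()
        return tuple(r for r in self.rules if r.anchor == anchor)

    def rule(self, warhead_class: str) -> WarheadRule:
        for r in self.rules:
            if r.warhead_class == warhead_class:
                return r
        raise KeyError(warhead_class)

    def variant_frequencies(self) -> list[int]:
        """The per-core-variant benchmark counts, flattened."""
        return [f for r in self.rules for f in r.frequencies]

    def class_frequencies(self) -> pd.DataFrame:
        rows = [(r.reaction_type, r.warhead_class, r.frequency)
                for r in sorted(self.rules, key=lambda r: -r.priority)]
        return pd.DataFrame(rows, columns=["reaction_type", "warhead_class",
                                           "frequency"])


_DEFAULT_TAXONOMY: WarheadTaxonomy | None = None


def default_taxonomy() -> WarheadTaxonomy:
    global _DEFAULT_TAXONOMY
    if _DEFAULT_TAXONOMY is None:
        _DEFAULT_TAXONOMY = WarheadTaxonomy.default()
    return _DEFAULT_TAXONOMY


def _prepared(mol: Chem.Mol) -> Chem.Mol:
    """Sanitize a copy as far as possible (pose-derived graphs may be rough)."""
    m = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(m)
    except Exception:
        m = Chem.Mol(mol)
        m.UpdatePropertyCache(strict=False)
        Chem.SetAromaticity(m)
    return m


def classify(ligand: Chem.Mol, anchor: str,
             taxonomy: WarheadTaxonomy | None = None,
             link_atom_index: int | None = None) -> ClassificationResult:
    """Assign a ligand/anchor pair to its warhead class.

    Rules are tried in priority order; within a rule, if several core
    matches exist and the covalent link atom is known, the match containing
    (or nearest in bond count to) the link atom wins.  Returns an
    ``Unclassified`` result — not an exception — when no rule matches.
    """
    taxonomy = taxonomy or default_taxonomy()
    mol = _prepared(ligand)
    for rule in taxonomy.rules_for_anchor(anchor):
        for pattern in rule.core_patterns:
            matches = mol.GetSubstructMatches(pattern.query(), uniquify=True)
            if not matches:
                continue
            match = _pick_match(mol, matches, link_atom_index)
            return ClassificationResult(
                warhead_class=rule.warhead_class,
                reaction_class=rule.reaction_class,
                reaction_type=rule.reaction_type,
                matched_atoms=frozenset(match),
                link_atom_index=match[min(pattern.link_atom_pos,
                                          len(match) - 1)],
            )
    return ClassificationResult(warhead_class=UNCLASSIFIED,
                                reaction_class=None)


def _pick_match(mol: Chem.Mol, matches: Sequence[tuple[int, ...]],
                link_atom_index: int | None) -> tuple[int, ...]:
    if link_atom_index is None or len(matches) == 1:
        return matches[0]
    dmat = Chem.GetDistanceMatrix(mol)
    return min(matches,
               key=lambda m: min(dmat[link_atom_index][i] for i in m))


# ---------------------------------------------------------------------------
# reaction templates


def load_reaction(source: str | Path | AllChem.ChemicalReaction
                  ) -> AllChem.ChemicalReaction:
    """Load a reaction from SMARTS text, an MDL RXN file, or pass through."""
    if isinstance(source, AllChem.ChemicalReaction):
        return source
    text = str(source)
    if text.endswith(".rxn") or Path(text).exists():
        from rdkit import rdBase
        with rdBase.BlockLogs():
            rxn = AllChem.ReactionFromRxnFile(str(source))
    else:
        rxn = AllChem.ReactionFromSmarts(text)
    if rxn is None:
        raise ValueError(f"could not parse reaction from {source!r}")
    rxn.Initialize()
    return rxn


def reverse_reaction_smarts(reaction_smarts: str) -> str:
    """Reverse a reaction SMARTS (products become reactants)."""
    left, right = reaction_smarts.split(">>")
    return f"{right}>>{left}"


def _count_warhead_matches(rxn: AllChem.ChemicalReaction,
                           ligand: Chem.Mol) -> int:
    template = rxn.GetReactantTemplate(0)
    return len(ligand.GetSubstructMatches(template, uniquify=True))


def apply_reaction(pre_ligand: Chem.Mol,
                   rxn: str | Path | AllChem.ChemicalReaction,
                   anchor: str,
                   taxonomy: WarheadTaxonomy | None = None,
                   extra_reactants: Sequence[Chem.Mol] = (),
                   allow_ambiguous: bool = False) -> AdductResult:
    """Apply a warhead reaction template, forming the covalent adduct.

    The anchor side chain is represented by a minimal nucleophile fragment
    (methanethiol for Cys, methanol for Ser) whose S/O maps onto the anchor
    link atom.  The template's first reactant pattern must match the ligand
    exactly once; zero matches raise "template does not apply", several
    raise "ambiguous match" unless ``allow_ambiguous`` (then the first
    match is transformed).
    """
    taxonomy = taxonomy or default_taxonomy()
    anchor_name = getattr(anchor, "residue_name", str(anchor)).upper()
    if anchor_name not in taxonomy.anchor_nucleophile:
        raise ValueError(f"unknown anchor {anchor_name!r}")
    rxn = load_reaction(rxn)
    ligand = _prepared(pre_ligand)

    n = _count_warhead_matches(rxn, ligand)
    if n == 0:
        raise TemplateError("template does not apply: no warhead match")
    if n > 1 and not allow_ambiguous:
        raise TemplateError(
            f"ambiguous match: warhead pattern matches {n} times "
            "(a unique match is required)")

    reactants = [ligand]
    if rxn.GetNumReactantTemplates() >= 2 and not extra_reactants:
        nuc = Chem.MolFromSmiles(taxonomy.anchor_nucleophile[anchor_name])
        reactants.append(nuc)
    reactants.extend(extra_reactants)
    if len(reactants) != rxn.GetNumReactantTemplates():
        raise TemplateError(
            f"template expects {rxn.GetNumReactantTemplates()} reactants, "
            f"got {len(reactants)}")

    product_sets = rxn.RunReactants(tuple(reactants))
    if not product_sets:
        raise TemplateError("template does not apply: reaction produced "
                            "no products")
    products = []
    for mol in product_sets[0]:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(mol, catchErrors=True)
        products.append(mol)
    adduct = max(products, key=lambda m: m.GetNumHeavyAtoms())
    leaving = tuple(m for m in products if m is not adduct)
    return AdductResult(adduct=adduct, leaving_groups=leaving)


def heavy_graph_signature(mol: Chem.Mol) -> str:
    """Canonical element-connectivity signature (bond orders and charges
    collapsed) for heavy-atom graph-isomorphism comparisons."""
    skel = Chem.RWMol()
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    remap = {idx: i for i, idx in enumerate(heavy)}
    for idx in heavy:
        atom = Chem.Atom(mol.GetAtomWithIdx(idx).GetAtomicNum())
        atom.SetNoImplicit(True)
        skel.AddAtom(atom)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            skel.AddBond(remap[i], remap[j], Chem.BondType.SINGLE)
    out = skel.GetMol()
    out.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(out)


def graphs_isomorphic(a: Chem.Mol, b: Chem.Mol) -> bool:
    """Heavy-atom element+connectivity isomorphism."""
    return heavy_graph_signature(a) == heavy_graph_signature(b)


# ---------------------------------------------------------------------------
# bookkeeping


def tabulate_frequencies(entries: Iterable, by: str = "warhead_class"
                         ) -> pd.DataFrame:
    """Count classified entries per warhead class (or reaction class).

    Each entry is counted exactly once; the counts partition the entry set.
    """
    classes = []
    for e in entries:
        value = getattr(e, by, None) if not isinstance(e, str) else e
        classes.append(value if value else UNCLASSIFIED)
    counts = pd.Series(classes, dtype="object").value_counts()
    table = counts.rename_axis(by).reset_index(name="count")
    return table.sort_values("count", ascending=False, ignore_index=True)
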