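"""Anchor-site descriptors: solvent accessibility and side-chain torsion.

The flexibility and exposure of the nucleophilic anchor residue shape
covalent docking accuracy: a buried, conformationally locked cysteine
constrains the warhead, an exposed one does not.  Two descriptors capture
this: the solvent accessible surface area (SASA) of the anchor residue and
the N-CA-CB-SG (Cys) or N-CA-CB-OG (Ser) side-chain dihedral.

SASA uses the Shrake-Rupley rolling-probe construction: each atom is
covered with quasi-uniform test points on its solvent-expanded sphere
(radius + probe) and the accessible area is the fraction of points not
buried inside any neighbor's expanded sphere.  The atomic radius set ships
as editable config (``data/radii.yaml``); absolute areas depend on that
choice.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from covbench.datamodel import BenchmarkEntry

__all__ = [
    "SiteDescriptor",
    "shrake_rupley_sasa",
    "anchor_sasa",
    "dihedral_angle",
    "anchor_dihedral",
    "accuracy_by_feature",
    "KINASE_DOMAINS",
    "load_radii",
]

PROBE_RADIUS = 1.4   # A, water probe
N_SPHERE_POINTS = 960

KINASE_DOMAINS = (
    "Remote-Cys", "Beta4-4", "Catalytic-3", "Hinge", "DFG-3",
    "Extended front pocket", "Front pocket", "P-loop",
)


@dataclass(frozen=True)
class SiteDescriptor:
    entry_id: str
    sasa: float                       # A^2, anchor residue, ligand-free
    dihedral: float                   # degrees, (-180, 180]
    kinase_domain: str | None = None

    def __post_init__(self) -> None:
        if self.sasa < 0:
            raise ValueError("SASA must be non-negative")
        if not (-180.0 < self.dihedral <= 180.0):
            raise ValueError("dihedral must lie in (-180, 180]")


def load_radii(path: str | Path | None = None) -> tuple[dict[str, float], float]:
    """Atomic radius table and probe radius from config."""
    if path is None:
        ref = importlib.resources.files("covbench") / "data" / "radii.yaml"
        with importlib.resources.as_file(ref) as p:
            data = yaml.safe_load(Path(p).read_text())
    else:
        data = yaml.safe_load(Path(path).read_text())
    radii = {str(k).upper(): float(v) for k, v in data["radii"].items()}
    return radii, float(data.get("probe_radius", PROBE_RADIUS))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * np.arange(n)
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(coords: np.ndarray, radii: Sequence[float],
                       probe: float = PROBE_RADIUS,
                       n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Per-atom solvent accessible surface area (A^2).

    ``coords`` is (n, 3); ``radii`` the per-atom van der Waals radii.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(list(radii), dtype=float)
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("coords and radii length mismatch")
    n = coords.shape[0]
    expanded = radii + probe
    sphere = _fibonacci_sphere(n_points)
    areas = np.empty(n)
    # neighbor cut: two expanded spheres can only occlude within this reach
    max_reach = expanded.max() + expanded[:, None]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere       # (m, 3)
        neigh = np.flatnonzero((d2[i] < max_reach[i] ** 2)
                               & (np.arange(n) != i))
        accessible = np.ones(len(pts), dtype=bool)
        for j in neigh:
            dj2 = ((pts - coords[j]) ** 2).sum(-1)
            accessible &= dj2 > expanded[j] ** 2
        areas[i] = (accessible.mean() * 4.0 * math.pi * expanded[i] ** 2)
    return areas


def anchor_sasa(entry: BenchmarkEntry, probe: float = PROBE_RADIUS,
                n_points: int = N_SPHERE_POINTS,
                radii_table: dict[str, float] | None = None) -> float:
    """SASA (A^2) of the anchor residue within the ligand-free receptor.

    The covalent ligand is excluded before the calculation, so the value
    describes the apo-like exposure of the nucleophile.
    """
    if entry.receptor_atoms is None or len(entry.receptor_atoms) == 0:
        raise ValueError("entry carries no receptor coordinates")
    table = radii_table or load_radii()[0]
    rec = entry.receptor_atoms
    required = {"CYS": ("N", "CA", "CB", "SG"), "SER": ("N", "CA", "CB", "OG")}
    anchor_mask = ((rec["chain"] == entry.anchor.chain)
                   & (rec["resnum"] == entry.anchor.residue_number)
                   & (rec["resname"] == entry.anchor.residue_name))
    present = set(rec.loc[anchor_mask, "name"])
    for atom in required[entry.anchor.residue_name]:
        if atom not in present:
            raise ValueError(
                f"anchor residue missing atom {atom!r}; cannot compute SASA")
    heavy = rec[rec["element"].str.upper() != "H"].reset_index(drop=True)
    coords = heavy[["x", "y", "z"]].to_numpy(dtype=float)
    radii = np.array([table.get(e.upper(), table.get("DEFAULT", 1.8))
                      for e in heavy["element"]])
    per_atom = shrake_rupley_sasa(coords, radii, probe=probe,
                                  n_points=n_points)
    mask = ((heavy["chain"] == entry.anchor.chain)
            & (heavy["resnum"] == entry.anchor.residue_number)
            & (heavy["resname"] == entry.anchor.residue_name))
    return float(per_atom[mask.to_numpy()].sum())


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed IUPAC torsion (degrees) of four points, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    if np.linalg.norm(np.cross(b0, b1)) < 1e-9 \
            or np.linalg.norm(np.cross(b1, b2)) < 1e-9:
        raise ValueError("degenerate (collinear) geometry: torsion undefined")
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1u, v), w))
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0 or math.isclose(angle, -180.0, abs_tol=1e-12):
        angle = 180.0
    return angle


def anchor_dihedral(entry: BenchmarkEntry) -> float:
    """N-CA-CB-SG (Cys) / N-CA-CB-OG (Ser) torsion of the anchor residue."""
    names = ("N", "CA", "CB", entry.anchor.link_atom)
    try:
        pts = [entry.anchor.atoms[n] for n in names]
    except KeyError as exc:
        raise ValueError(
            f"anchor residue missing atom {exc.args[0]!r}") from exc
    return dihedral_angle(*pts)


def accuracy_by_feature(results: pd.DataFrame,
                        descriptors: pd.DataFrame,
                        feature: str = "sasa",
                        bins: Sequence[float] | float | None = None
                        ) -> pd.DataFrame:
    """Median best-scored RMSD per tool per feature bin.

    Defaults: 10 A^2 bins for SASA, 30 degree bins for the dihedral;
    ``kinase_domain`` is treated categorically.  Empty bins are reported as
    missing (NaN), not zero.
    """
    joined = results.merge(descriptors, on="entry_id", how="inner")
    if len(joined) == 0:
        raise ValueError("no overlap between results and descriptors")
    if feature == "kinase_domain":
        joined["bin"] = joined["kinase_domain"]
    else:
        values = joined[feature].astype(float)
        if bins is None:
            width = 10.0 if feature == "sasa" else 30.0
        elif np.isscalar(bins):
            width = float(bins)
        else:
            width = None
        if width is not None:
            lo = 0.0 if feature == "sasa" else -180.0
            hi = float(np.ceil(values.max() / width) * width) \
                if feature == "sasa" else 180.0
            edges = np.arange(lo, hi + width, width)
        else:
            edges = np.asarray(bins, dtype=float)
        joined["bin"] = pd.cut(values, edges, include_lowest=True)
    table = (joined.groupby(["tool_id", "bin"], observed=False)["s1"]
             .agg(median_s1="median", n="count").reset_index())
    return table
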