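"""Aggregate per-complex results into tool-selection criteria.

Three criteria summarize a docking tool over a benchmark:

* **precision** ``P(i, x)`` — the median across classes (warhead classes or
  receptor types) of the within-class median RMSD of tool *i* under
  measurement *x* (best-scored or best-sampled pose).  A median of medians:
  robust to the very uneven class sizes of covalent benchmarks.  Lower is
  better.
* **generality** — for every (class, subgroup) cell (subgroups are UniProt
  accessions or warhead cores) each tool's median RMSD is computed and the
  tool(s) attaining the minimum receive a *mark*; total marks measure how
  often a tool is the best choice.  ``G(i, x)`` additionally normalizes
  marks per class by the number of structures evaluated, x100.  Higher is
  better.
* **robustness** — the sample standard deviation of a tool's RMSDs over
  the whole benchmark.  Lower (narrower) is more robust.

Profiling counts classify per-entry outcomes across tools: S-count
(S1 <= tau), F-count (S1 > tau and S2 > tau), and the cross-tool S-Only /
F-Only / S>=2 / F>=2 breakdown.  Pairwise significance uses the
Mann-Whitney rank test (tie-corrected, two-sided), reported raw and
Holm-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from covbench.pose_metrics import ComplexResult

__all__ = [
    "GroupingSpec",
    "ToolReport",
    "results_to_frame",
    "outer_median",
    "precision",
    "precision_from_medians",
    "generality",
    "robustness",
    "profile",
    "p_deviation_distribution",
    "compare_tools",
    "pairwise_tests",
    "holm_adjust",
    "heatmap_table",
    "tool_report",
]

Measurement = Literal["best_scored", "best_sampled"]
_MEASUREMENT_COLUMN = {"best_scored": "s1", "best_sampled": "s2"}

GREEN_ANCHOR = 1.0   # A; at or below -> deep green
RED_ANCHOR = 5.0     # A; at or above -> deep red
_DEEP_GREEN = (0, 100, 0)
_DEEP_RED = (139, 0, 0)


@dataclass(frozen=True)
class GroupingSpec:
    """How entries are grouped for precision/generality.

    ``axis`` is the class column (warhead_class or receptor_type);
    ``subgroup`` the finer key used for generality marks (uniprot_id or
    warhead_core).
    """

    axis: str = "warhead_class"
    subgroup: str = "uniprot_id"

    def __post_init__(self) -> None:
        if self.axis not in ("warhead_class", "receptor_type"):
            raise ValueError("axis must be warhead_class or receptor_type")
        if self.subgroup not in ("uniprot_id", "warhead_core"):
            raise ValueError("subgroup must be uniprot_id or warhead_core")


@dataclass
class ToolReport:
    """Per-tool aggregates for one measurement."""

    tool_id: str
    measurement: str
    class_medians: dict[str, float]
    precision: float
    robustness: float | None = None
    generality_marks: int | None = None
    generality_score: float | None = None
    s_count: int | None = None
    f_count: int | None = None
    s_only: int | None = None
    f_only: int | None = None
    s_ge2: int | None = None
    f_ge2: int | None = None

    def to_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k != "class_medians"}
        return row


def results_to_frame(results: Iterable[ComplexResult],
                     metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate ComplexResults, optionally joining benchmark metadata
    (warhead_class, receptor_type, uniprot_id, ...) on entry_id."""
    rows = [{
        "tool_id": r.tool_id, "entry_id": r.entry_id,
        "s1": r.s1, "s2": r.s2, "smax": r.smax,
        "p_deviation": r.p_deviation, "tau": r.tau,
        "success": r.success, "failure": r.failure,
    } for r in results]
    frame = pd.DataFrame(rows)
    if metadata is not None:
        meta_cols = [c for c in metadata.columns if c != "tool_id"]
        frame = frame.merge(metadata[meta_cols].drop_duplicates("entry_id"),
                            on="entry_id", how="left")
    return frame


def _measurement_column(frame: pd.DataFrame, x: Measurement) -> str:
    try:
        col = _MEASUREMENT_COLUMN[x]
    except KeyError:
        raise ValueError(f"unknown measurement {x!r}") from None
    if col not in frame.columns:
        raise ValueError(f"results frame lacks column {col!r}")
    return col


def outer_median(values: Sequence[float]) -> float:
    """Median with the even-length rule (mean of the two central values)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median of an empty sequence")
    return float(np.median(arr))


precision_from_medians = outer_median


def precision(frame: pd.DataFrame, grouping: GroupingSpec,
              x: Measurement = "best_scored"
              ) -> tuple[pd.Series, float]:
    """Per-class median RMSDs and their outer median P(i, x).

    ``frame`` holds one tool's results joined with metadata.  Classes with
    no results are omitted from the outer median with a warning.
    """
    col = _measurement_column(frame, x)
    if frame[grouping.axis].isna().any():
        missing = int(frame[grouping.axis].isna().sum())
        warnings.warn(f"{missing} results lack a {grouping.axis}; omitted")
        frame = frame.dropna(subset=[grouping.axis])
    if len(frame) == 0:
        raise ValueError("no results with class labels")
    medians = frame.groupby(grouping.axis)[col].median()
    return medians, outer_median(medians.to_numpy())


def _check_common_entries(frame: pd.DataFrame) -> None:
    sets = frame.groupby("tool_id")["entry_id"].apply(frozenset)
    if len(set(sets)) > 1:
        raise ValueError(
            "tools were evaluated on different entry sets; "
            "cross-tool comparison is invalid")


def generality(frame: pd.DataFrame, grouping: GroupingSpec,
               x: Measurement = "best_scored",
               tie_tolerance: float = 0.0) -> pd.DataFrame:
    """Mark-the-minimum generality over (class, subgroup) cells.

    Returns a per-tool frame with total ``marks`` and the normalized
    ``score`` = sum over classes of (marks in class / structures of that
    class for the tool) x 100.  All minimizers of a cell are marked (ties
    are not split).
    """
    col = _measurement_column(frame, x)
    _check_common_entries(frame)
    sub = frame.dropna(subset=[grouping.axis, grouping.subgroup])
    cell = (sub.groupby([grouping.axis, grouping.subgroup, "tool_id"])[col]
            .median().reset_index(name="median_rmsd"))
    tools = sorted(frame["tool_id"].unique())
    marks = {t: 0 for t in tools}
    class_marks: dict[tuple[str, str], int] = {}
    for (cls, _sg), grp in cell.groupby([grouping.axis, grouping.subgroup]):
        best = grp["median_rmsd"].min()
        for t in grp.loc[grp["median_rmsd"] <= best + tie_tolerance,
                         "tool_id"]:
            marks[t] += 1
            class_marks[(t, cls)] = class_marks.get((t, cls), 0) + 1
    n_ij = sub.groupby(["tool_id", grouping.axis])["entry_id"].nunique()
    rows = []
    for t in tools:
        score = 0.0
        for cls in sub[grouping.axis].unique():
            m = class_marks.get((t, cls), 0)
            n = n_ij.get((t, cls), 0)
            if n:
                score += m / n * 100.0
        rows.append({"tool_id": t, "marks": marks[t], "score": score})
    return pd.DataFrame(rows)


def robustness(frame: pd.DataFrame, x: Measurement = "best_scored") -> float:
    """Sample standard deviation (ddof=1) of one tool's RMSDs."""
    col = _measurement_column(frame, x)
    vals = frame[col].dropna().to_numpy()
    if len(vals) < 2:
        raise ValueError("robustness undefined for fewer than 2 results")
    return float(np.std(vals, ddof=1))


def profile(frame: pd.DataFrame, tau: float | None = None) -> pd.DataFrame:
    """Cross-tool success/failure profiling counts.

    success: S1 <= tau; failure: S1 > tau and S2 > tau.  ``s_only`` counts
    entries where only that tool succeeded, ``s_ge2`` entries where it
    succeeded together with at least one other tool; analogously for
    failures.  Requires >= 2 tools on a common entry set.
    """
    tools = sorted(frame["tool_id"].unique())
    if len(tools) < 2:
        raise ValueError("profiling needs at least 2 tools")
    _check_common_entries(frame)
    f = frame.copy()
    if tau is not None:
        f["success"] = f["s1"] <= tau
        f["failure"] = (f["s1"] > tau) & (f["s2"] > tau)
    succ = f.pivot(index="entry_id", columns="tool_id", values="success")
    fail = f.pivot(index="entry_id", columns="tool_id", values="failure")
    rows = []
    for t in tools:
        others_s = succ.drop(columns=t).sum(axis=1)
        others_f = fail.drop(columns=t).sum(axis=1)
        rows.append({
            "tool_id": t,
            "s_count": int(succ[t].sum()),
            "f_count": int(fail[t].sum()),
            "s_only": int((succ[t] & (others_s == 0)).sum()),
            "f_only": int((fail[t] & (others_f == 0)).sum()),
            "s_ge2": int((succ[t] & (others_s >= 1)).sum()),
            "f_ge2": int((fail[t] & (others_f >= 1)).sum()),
        })
    return pd.DataFrame(rows)


def p_deviation_distribution(frame: pd.DataFrame,
                             bin_width: float = 0.5) -> pd.DataFrame:
    """Binned counts of the P-deviation (S1 - S2) per tool."""
    if len(frame) == 0:
        raise ValueError("no results")
    top = max(float(frame["p_deviation"].max()), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    if edges[-1] < top:
        edges = np.append(edges, edges[-1] + bin_width)
    rows = []
    for tool, grp in frame.groupby("tool_id"):
        counts, _ = np.histogram(grp["p_deviation"].to_numpy(), bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"tool_id": tool, "bin_low": lo, "bin_high": hi,
                         "count": int(c)})
    return pd.DataFrame(rows)


def compare_tools(values_a: Sequence[float], values_b: Sequence[float]
                  ) -> tuple[float, float]:
    """Two-sided, tie-corrected Mann-Whitney U-test on two RMSD samples.

    Degenerate all-equal samples return p = 1 (with a warning) by
    convention.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 results per tool")
    if np.all(np.concatenate([a, b]) == a[0]):
        warnings.warn("all values equal in both samples; p = 1 by convention")
        return float(len(a) * len(b) / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def pairwise_tests(frame: pd.DataFrame, x: Measurement = "best_scored"
                   ) -> pd.DataFrame:
    """All pairwise Mann-Whitney tests between tools, raw + Holm-adjusted."""
    col = _measurement_column(frame, x)
    tools = sorted(frame["tool_id"].unique())
    rows = []
    for i, a in enumerate(tools):
        for b in tools[i + 1:]:
            u, p = compare_tools(
                frame.loc[frame.tool_id == a, col],
                frame.loc[frame.tool_id == b, col])
            rows.append({"tool_a": a, "tool_b": b, "U": u, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p"])
    return out


def _interpolate_color(value: float, green_anchor: float,
                       red_anchor: float) -> str:
    t = (value - green_anchor) / (red_anchor - green_anchor)
    t = min(1.0, max(0.0, t))
    rgb = tuple(round(g + t * (r - g)) for g, r in zip(_DEEP_GREEN, _DEEP_RED))
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def heatmap_table(medians: pd.DataFrame,
                  green_anchor: float = GREEN_ANCHOR,
                  red_anchor: float = RED_ANCHOR
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Color-code a (class x tool) median-RMSD matrix.

    Linear interpolation from deep green at ``green_anchor`` to deep red at
    ``red_anchor``, clamped at both anchors.  Returns (matrix, hex-color
    matrix).
    """
    colors = medians.map(
        lambda v: _interpolate_color(float(v), green_anchor, red_anchor))
    return medians, colors


def tool_report(frame: pd.DataFrame, grouping: GroupingSpec,
                x: Measurement = "best_scored",
                tau: float | None = None) -> list[ToolReport]:
    """Assemble full per-tool reports for one measurement."""
    tools = sorted(frame["tool_id"].unique())
    gen = generality(frame, grouping, x) if len(tools) > 1 else None
    prof = profile(frame, tau) if len(tools) > 1 else None
    reports = []
    for t in tools:
        sub = frame[frame.tool_id == t]
        medians, p = precision(sub, grouping, x)
        rep = ToolReport(
            tool_id=t, measurement=x,
            class_medians=medians.to_dict(), precision=p,
            robustness=robustness(sub, x) if len(sub) >= 2 else None)
        if gen is not None:
            row = gen[gen.tool_id == t].iloc[0]
            rep.generality_marks = int(row["marks"])
            rep.generality_score = float(row["score"])
        if prof is not None:
            row = prof[prof.tool_id == t].iloc[0]
            for k in ("s_count", "f_count", "s_only", "f_only",
                      "s_ge2", "f_ge2"):
                setattr(rep, k, int(row[k]))
        reports.append(rep)
    return reports
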