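"""Shipped reference tables from the published four-tool benchmark.

Per-class median RMSDs (best-scored and best-sampled pose) for MOE, GOLD,
CovDock and ICM-Pro over the curated 330-complex covalent benchmark,
grouped by warhead class and by receptor type.  These are worked-example
inputs: feeding a per-class median column into the outer median reproduces
the published overall precision values.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

__all__ = ["load_reference_medians", "REFERENCE_TOOLS"]

REFERENCE_TOOLS = ("MOE", "GOLD", "CovDock", "ICM-Pro")


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("covbench") / "data" / "reference" / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(Path(path))


def load_reference_medians(axis: str = "warhead_class") -> pd.DataFrame:
    """Reference per-class median RMSD table for one grouping axis.

    ``axis`` is ``warhead_class`` or ``receptor_type``.  Columns:
    the class label, ``n`` (structures per class) and one column per
    (measurement, tool) pair named ``best_scored_<tool>`` /
    ``best_sampled_<tool>``.
    """
    if axis == "warhead_class":
        return _load("warhead_medians.csv")
    if axis == "receptor_type":
        return _load("receptor_medians.csv")
    raise ValueError("axis must be warhead_class or receptor_type")
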