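"""Measure registry: map analysis measure names to per-cell columns."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_cohort import MRNA_MEASURES

__all__ = ["cell_values", "subject_means", "is_mrna_measure", "KNOWN_MEASURES"]

KNOWN_MEASURES = (
    "cytoplasmic_rbfox1",
    "nuclear_rbfox1",
    "total_rbfox1",
    "pv_intensity",
    "cn_ratio",
    "pv_grain_density",
    "vamp1_grain_density",
)


def cell_values(cells: pd.DataFrame, measure: str) -> pd.Series:
    """Per-cell values of a named measure."""
    if measure == "cytoplasmic_rbfox1":
        return cells["cytoplasmic_intensity"]
    if measure == "nuclear_rbfox1":
        return cells["nuclear_intensity"]
    if measure == "total_rbfox1":
        return cells["body_intensity"]
    if measure == "pv_intensity":
        return cells["pv_intensity"]
    if measure == "cn_ratio":
        return cells["cytoplasmic_intensity"] / cells["nuclear_intensity"]
    if measure == "pv_grain_density":
        return cells["pv_grain_count"] / cells["cytoplasm_area"]
    if measure == "vamp1_grain_density":
        return cells["vamp1_grain_count"] / cells["cytoplasm_area"]
    raise KeyError(f"unknown measure {measure!r}")


def subject_means(cells: pd.DataFrame, measure: str,
                  subtype: str | None = "PVI") -> pd.Series:
    """Mean of a measure over each subject's sampled cells (PVIs by default)."""
    sel = cells if subtype is None else cells[cells.subtype == subtype]
    vals = cell_values(sel, measure)
    out = vals.groupby(sel.subject_id).mean()
    if out.isna().any() or not np.isfinite(out).all():
        raise ValueError(f"non-finite subject means for {measure!r}")
    return out


def is_mrna_measure(measure: str) -> bool:
    return measure in MRNA_MEASURES
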