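"""Marker-flag gating into phenotype labels and subset counting.

Gating precedence on the mIF assay: panCK > CD3 lineage > CD20 > CD68 >
other. Within the CD3 lineage, FOXP3+ gates to t_reg, otherwise CD8+ to
t_cytotoxic, otherwise t_helper (there is no CD4 in the panel). On the
double-IHC assay only CD8 and Ki67 are read: CD8+Ki67+ is
activated_cytotoxic, CD8+Ki67- is t_cytotoxic, anything else is other.

The pooled "lymphocytes" group supports two modes. "strict-literal"
follows the printed composition formula — CD3+CD8-FOXP3- + CD3+CD8+FOXP3-
+ CD3+CD8-FOXP3+ + CD20+ B cells — which excludes the CD3+CD8+FOXP3+
combination; "inclusive" adds it. The t_reg class always includes it.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core import ANALYSED_COMPARTMENTS, MARKERS, SUBSETS, VocabularyError
from .io import SlideCellMap

FORMULA_MODES = ("strict-literal", "inclusive")


def gate_cell(markers: Mapping[str, int], assay: str = "mif") -> str:
    """Gate one cell's marker flags into a phenotype label."""
    for key in markers:
        if key not in MARKERS:
            raise VocabularyError(f"unknown marker {key!r}")
    get = lambda m: bool(markers.get(m, 0))
    if assay == "cd8ki67":
        if get("CD8") and get("Ki67"):
            return "activated_cytotoxic"
        if get("CD8"):
            return "t_cytotoxic"
        return "other"
    if get("panCK"):
        return "dcis_cell"
    if get("CD3"):
        if get("FOXP3"):
            return "t_reg"
        if get("CD8"):
            return "t_cytotoxic"
        return "t_helper"
    if get("CD20"):
        return "b_cell"
    if get("CD68"):
        return "macrophage"
    return "other"


def gate_table(cells: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`gate_cell` over a validated cell table."""
    m = {k: cells[k].to_numpy(bool) for k in MARKERS}
    is_mif = cells["assay"].to_numpy() == "mif"
    mif_label = np.select(
        [
            m["panCK"],
            m["CD3"] & m["FOXP3"],
            m["CD3"] & m["CD8"],
            m["CD3"],
            m["CD20"],
            m["CD68"],
        ],
        ["dcis_cell", "t_reg", "t_cytotoxic", "t_helper", "b_cell", "macrophage"],
        default="other",
    )
    ihc_label = np.select(
        [m["CD8"] & m["Ki67"], m["CD8"]],
        ["activated_cytotoxic", "t_cytotoxic"],
        default="other",
    )
    return pd.Series(np.where(is_mif, mif_label, ihc_label), index=cells.index, name="phenotype")


def lymphocyte_mask(cells: pd.DataFrame, labels: pd.Series, mode: str = "strict-literal") -> pd.Series:
    """Membership of the pooled lymphocyte group among mIF cells."""
    return subset_masks(cells, labels, mode)["lymphocytes"]


def subset_masks(
    cells: pd.DataFrame, labels: pd.Series, mode: str = "strict-literal"
) -> dict[str, pd.Series]:
    """Boolean membership per immune subset (cells may belong to several)."""
    if mode not in FORMULA_MODES:
        raise VocabularyError(f"unknown formula mode {mode!r}")
    lab = labels.to_numpy()
    is_mif = cells["assay"].to_numpy() == "mif"
    is_ihc = cells["assay"].to_numpy() == "cd8ki67"
    cd8 = cells["CD8"].to_numpy(bool)
    foxp3 = cells["FOXP3"].to_numpy(bool)
    th = lab == "t_helper"
    tc = lab == "t_cytotoxic"
    tr = lab == "t_reg"
    if mode == "inclusive":
        t_terms = (th | tc | tr) & is_mif
    else:
        t_terms = th | (tc & is_mif & ~foxp3) | (tr & ~cd8)
    raw = {
        "lymphocytes": (t_terms | (lab == "b_cell")) & is_mif,
        "t_all": (th | tc | tr) & is_mif,
        "b_cell": (lab == "b_cell") & is_mif,
        "t_helper": th & is_mif,
        "t_cytotoxic": tc & is_mif,
        "t_reg": tr & is_mif,
        "macrophage": (lab == "macrophage") & is_mif,
        "activated_cytotoxic": (lab == "activated_cytotoxic") & is_ihc,
    }
    return {k: pd.Series(v, index=cells.index) for k, v in raw.items()}


def count_subsets(
    slide: SlideCellMap, mode: str = "strict-literal"
) -> dict[tuple[str, str], int]:
    """Counts per (subset, compartment) over stroma and epithelium only."""
    cells = slide.cells
    labels = gate_table(cells)
    masks = subset_masks(cells, labels, mode)
    comp = cells["compartment"].to_numpy()
    out: dict[tuple[str, str], int] = {}
    for c in ANALYSED_COMPARTMENTS:
        in_comp = comp == c
        for subset in SUBSETS:
            out[(subset, c)] = int((masks[subset].to_numpy() & in_comp).sum())
    return out
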