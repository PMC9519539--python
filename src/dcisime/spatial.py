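"""Spatial summaries: compartment densities, pairwise ratios and the
DCIS proximity index (immune cells within a radius of any DCIS cell,
divided by the number of DCIS cells)."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    ANALYSED_COMPARTMENTS,
    FOXP3_DEPENDENT_SUBSETS,
    SUBSETS,
    ConsistencyError,
    VocabularyError,
)
from .io import SlideCellMap
from .phenotyping import count_subsets, gate_table, subset_masks

DEFAULT_PROXIMITY_RADIUS_UM = 25.0


def compute_densities(
    slide: SlideCellMap,
    mode: str = "strict-literal",
    foxp3_assessable: bool = True,
) -> pd.DataFrame:
    """One row per subset × {stroma, epithelium}: count, area, cells/mm².

    Subsets whose gating depends on an unassessable marker are emitted
    with missing count/density rather than zero. Compartments with zero
    area and zero count are omitted with a warning; a nonzero count in a
    zero-area compartment is a consistency error.
    """
    counts = count_subsets(slide, mode=mode)
    rows = []
    for comp in ANALYSED_COMPARTMENTS:
        area = slide.geometry.area(comp)
        for subset in SUBSETS:
            count = counts[(subset, comp)]
            if area == 0.0:
                if count > 0:
                    raise ConsistencyError(
                        f"{count} {subset} cells in zero-area compartment {comp!r} "
                        f"(patient {slide.patient_id})"
                    )
                warnings.warn(
                    f"omitting {subset}/{comp} for {slide.patient_id}: zero area",
                    stacklevel=2,
                )
                continue
            missing = (not foxp3_assessable) and subset in FOXP3_DEPENDENT_SUBSETS
            rows.append(
                {
                    "patient_id": slide.patient_id,
                    "subset_id": subset,
                    "compartment": comp,
                    "count": np.nan if missing else count,
                    "area_mm2": area,
                    "density_cells_per_mm2": np.nan if missing else count / area,
                }
            )
    return pd.DataFrame(rows)


def compute_ratios(density_table: pd.DataFrame) -> pd.DataFrame:
    """All C(8,2)=28 unordered subset-pair density ratios per compartment.

    The numerator is the subset that comes earlier in the canonical
    order. 0/0 is missing (NaN); x/0 with x>0 is +inf (excluded from rank
    tests downstream via the missing-data policy).
    """
    unknown = set(density_table["subset_id"]) - set(SUBSETS)
    if unknown:
        raise VocabularyError(f"unknown subset ids {sorted(unknown)!r}")
    rows = []
    for (patient, comp), grp in density_table.groupby(["patient_id", "compartment"], sort=False):
        dens = grp.set_index("subset_id")["density_cells_per_mm2"]
        for num, den in itertools.combinations(SUBSETS, 2):
            if num not in dens.index or den not in dens.index:
                continue
            a, b = dens[num], dens[den]
            if np.isnan(a) or np.isnan(b):
                ratio = np.nan
            elif b == 0.0:
                ratio = np.nan if a == 0.0 else np.inf
            else:
                ratio = a / b
            rows.append(
                {
                    "patient_id": patient,
                    "compartment": comp,
                    "numerator_subset": num,
                    "denominator_subset": den,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def proximity_index(
    slide: SlideCellMap,
    subset_id: str,
    radius_um: float = DEFAULT_PROXIMITY_RADIUS_UM,
    mode: str = "strict-literal",
    inclusive_boundary: bool = True,
) -> dict:
    """Proximity-index row for one immune subset on the mIF assay.

    An immune cell counts once if its nearest DCIS-cell centroid lies
    within ``radius_um`` (closed boundary by default). Only mIF cells
    participate; debris/background cells are excluded.
    """
    if subset_id not in SUBSETS:
        raise VocabularyError(f"unknown subset {subset_id!r}")
    cells = slide.subset_cells("mif")
    labels = gate_table(cells)
    dcis = cells[(labels == "dcis_cell").to_numpy()]
    n_dcis = len(dcis)
    if n_dcis == 0:
        raise ConsistencyError(
            f"proximity index undefined: no DCIS cells on slide {slide.patient_id}"
        )
    mask = subset_masks(cells, labels, mode)[subset_id]
    mask &= cells["compartment"].isin(ANALYSED_COMPARTMENTS)
    immune = cells[mask.to_numpy()]
    if len(immune) == 0:
        n_within = 0
    else:
        tree = cKDTree(dcis[["x_um", "y_um"]].to_numpy(float))
        d, _ = tree.query(immune[["x_um", "y_um"]].to_numpy(float), k=1)
        n_within = int((d <= radius_um).sum() if inclusive_boundary else (d < radius_um).sum())
    return {
        "patient_id": slide.patient_id,
        "subset_id": subset_id,
        "radius_um": radius_um,
        "n_immune_within_radius": n_within,
        "n_dcis_cells": n_dcis,
        "proximity_index": n_within / n_dcis,
    }


def proximity_table(
    slide: SlideCellMap,
    subsets: tuple[str, ...] | None = None,
    radius_um: float = DEFAULT_PROXIMITY_RADIUS_UM,
    mode: str = "strict-literal",
) -> pd.DataFrame:
    """Proximity indices for the mIF subsets (activated_cytotoxic excluded:
    Ki67 is not in the mIF panel)."""
    if subsets is None:
        subsets = tuple(s for s in SUBSETS if s != "activated_cytotoxic")
    rows = [proximity_index(slide, s, radius_um=radius_um, mode=mode) for s in subsets]
    return pd.DataFrame(rows)
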