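"""Tertiary lymphoid structure detection from cell point patterns.

zone-TLS: a B-cell follicle (density-based cluster of gated b_cell
points) with an adjacent T-cell zone (enough T cells within a band of
the follicle convex hull). GC-TLS: a lymphoid aggregate whose core — the
inner fraction of its convex hull by area — is sufficiently Ki67+,
detected on the CD8/Ki67 double-stain assay (or on mIF cells where Ki67
was explicitly enabled).

The published structures were counted by pathologists; these thresholds
are algorithmic stand-ins, tuned to call seeded synthetic follicles and
nothing on homogeneous Poisson background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely import MultiPoint
from shapely.affinity import scale as affine_scale
from sklearn.cluster import DBSCAN

from .core import um2_to_mm2
from .io import SlideCellMap
from .phenotyping import gate_table


@dataclass
class TLSParams:
    eps_um: float = 30.0
    min_follicle: int = 20
    t_zone_um: float = 50.0
    min_t_zone: int = 30
    gc_core_area_fraction: float = 0.5
    gc_threshold: float = 0.3
    min_aggregate: int = 20


@dataclass
class TLSRecord:
    tls_id: str
    tls_type: str  # "zone" | "gc"
    centroid_x_um: float
    centroid_y_um: float
    n_core_cells: int
    n_t_zone_cells: int
    hull_area_mm2: float


def _clusters(points: np.ndarray, eps_um: float, min_size: int) -> list[np.ndarray]:
    """Density clusters with at least ``min_size`` members.

    DBSCAN runs with a permissive min_samples; the follicle size
    threshold is applied to whole clusters afterwards, so raising
    ``min_size`` can only drop clusters (monotone).
    """
    if len(points) < min_size:
        return []
    labels = DBSCAN(eps=eps_um, min_samples=3).fit(points).labels_
    out = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        idx = np.flatnonzero(labels == lab)
        if len(idx) >= min_size:
            out.append(idx)
    return out


def detect_zone_tls(slide: SlideCellMap, params: TLSParams | None = None) -> list[TLSRecord]:
    """Detect B-cell follicles with an adjacent T-cell zone (mIF cells)."""
    params = params or TLSParams()
    cells = slide.subset_cells("mif")
    labels = gate_table(cells)
    b = cells[(labels == "b_cell").to_numpy()][["x_um", "y_um"]].to_numpy(float)
    t_mask = labels.isin(["t_helper", "t_cytotoxic", "t_reg"]).to_numpy()
    t = cells[t_mask][["x_um", "y_um"]].to_numpy(float)
    t_points = shapely.points(t[:, 0], t[:, 1]) if len(t) else None
    records = []
    for i, idx in enumerate(_clusters(b, params.eps_um, params.min_follicle)):
        pts = b[idx]
        hull = MultiPoint(pts).convex_hull
        if t_points is None:
            n_t = 0
        else:
            n_t = int((shapely.distance(t_points, hull) <= params.t_zone_um).sum())
        if n_t < params.min_t_zone:
            continue
        c = hull.centroid
        records.append(
            TLSRecord(
                tls_id=f"{slide.patient_id}-zone-{len(records)}",
                tls_type="zone",
                centroid_x_um=c.x,
                centroid_y_um=c.y,
                n_core_cells=len(idx),
                n_t_zone_cells=n_t,
                hull_area_mm2=um2_to_mm2(hull.area),
            )
        )
    return records


def detect_gc_tls(slide: SlideCellMap, params: TLSParams | None = None, assay: str = "cd8ki67") -> list[TLSRecord]:
    """Detect aggregates with a Ki67+ germinal centre.

    Candidate cells are all marker-positive non-epithelial cells on the
    chosen assay. A candidate aggregate becomes GC-TLS when the Ki67+
    fraction of cells inside the hull core (inner
    ``gc_core_area_fraction`` of hull area, scaled about the centroid)
    reaches ``gc_threshold``; threshold 0 keeps every aggregate.
    """
    params = params or TLSParams()
    cells = slide.subset_cells(assay)
    labels = gate_table(cells)
    cand = cells[(labels != "dcis_cell").to_numpy() & (labels != "other").to_numpy()]
    xy = cand[["x_um", "y_um"]].to_numpy(float)
    ki67 = cand["Ki67"].to_numpy(bool)
    records = []
    for idx in _clusters(xy, params.eps_um, params.min_aggregate):
        pts = xy[idx]
        hull = MultiPoint(pts).convex_hull
        if hull.area == 0:
            continue
        f = np.sqrt(params.gc_core_area_fraction)
        core = affine_scale(hull, xfact=f, yfact=f, origin="centroid")
        inside = shapely.covers(core, shapely.points(pts[:, 0], pts[:, 1]))
        n_core = int(inside.sum())
        frac = float(ki67[idx][inside].mean()) if n_core else 0.0
        if frac < params.gc_threshold:
            continue
        c = hull.centroid
        records.append(
            TLSRecord(
                tls_id=f"{slide.patient_id}-gc-{len(records)}",
                tls_type="gc",
                centroid_x_um=c.x,
                centroid_y_um=c.y,
                n_core_cells=n_core,
                n_t_zone_cells=0,
                hull_area_mm2=um2_to_mm2(hull.area),
            )
        )
    return records


def tls_density(records: list[TLSRecord], analysed_area_mm2: float, tls_type: str, patient_id: str = "") -> dict:
    """TLS count per mm² of analysed area, for one TLS type."""
    if analysed_area_mm2 <= 0:
        raise ValueError("analysed_area_mm2 must be positive")
    n = sum(1 for r in records if r.tls_type == tls_type)
    return {
        "patient_id": patient_id,
        "tls_type": tls_type,
        "n_tls": n,
        "analysed_area_mm2": analysed_area_mm2,
        "density_per_mm2": n / analysed_area_mm2,
    }


def records_to_frame(records: list[TLSRecord]) -> pd.DataFrame:
    cols = ["tls_id", "tls_type", "centroid_x_um", "centroid_y_um",
            "n_core_cells", "n_t_zone_cells", "hull_area_mm2"]
    return pd.DataFrame([vars(r) for r in records], columns=cols)
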