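"""Cell-table and compartment-geometry containers plus CSV/GeoJSON I/O.

The on-disk formats are deliberately plain: cell tables are UTF-8 CSV with
one row per cell (``cell_id, x_um, y_um, assay, <marker 0/1 columns>,
compartment``) and geometry is GeoJSON with one polygon feature per
compartment piece carrying a ``compartment`` property. Coordinates are in
micrometres with the origin at the slide top-left and y increasing
downward; areas are reported in mm².
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .core import (
    ASSAYS,
    COMPARTMENTS,
    MARKERS,
    GeometryError,
    SchemaError,
    um2_to_mm2,
)

MANDATORY_COLUMNS = ("cell_id", "x_um", "y_um", "assay", "compartment")

#: Tie-break for points on shared boundaries: earlier wins.
COMPARTMENT_PRECEDENCE = ("epithelium", "debris", "stroma", "background")


@dataclass
class CompartmentGeometry:
    """Polygons (µm) and areas (mm²) per tissue compartment.

    Compartments without geometry may still carry an externally supplied
    area in ``area_mm2`` (mirrors accepting upstream segmentation output
    where only areas were exported).
    """

    polygons: dict[str, BaseGeometry] = field(default_factory=dict)
    area_mm2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, geom in self.polygons.items():
            if name not in COMPARTMENTS:
                raise GeometryError(f"unknown compartment {name!r}")
            if not geom.is_valid:
                raise GeometryError(f"invalid (self-intersecting?) polygon for {name!r}")
        for name, geom in self.polygons.items():
            derived = um2_to_mm2(geom.area)
            recorded = self.area_mm2.setdefault(name, derived)
            if abs(recorded - derived) > 1e-6:
                raise GeometryError(
                    f"area_mm2[{name!r}]={recorded} disagrees with polygon area {derived}"
                )
        for name, area in self.area_mm2.items():
            if area < 0:
                raise GeometryError(f"negative area for {name!r}")
        epi = self.polygons.get("epithelium")
        stroma = self.polygons.get("stroma")
        if epi is not None and stroma is not None:
            overlap = epi.intersection(stroma).area
            if um2_to_mm2(overlap) > 1e-6:
                raise GeometryError("stroma and epithelium interiors overlap")

    def area(self, compartment: str) -> float:
        return self.area_mm2.get(compartment, 0.0)


@dataclass
class PatientMetadata:
    """Clinical covariates for one patient; ``outcome`` is mandatory."""

    patient_id: str
    outcome: str  # "case" | "control"
    grade: int | None = None
    er: str | None = None
    pr: str | None = None
    her2: str | None = None
    cox2: str | None = None
    ki67_category: str | None = None
    fibrosis: str | None = None
    comedonecrosis: str | None = None
    foxp3_assessable: bool = True

    def __post_init__(self) -> None:
        if self.outcome not in ("case", "control"):
            raise SchemaError(f"outcome must be case/control, got {self.outcome!r}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise SchemaError(f"grade must be 1/2/3, got {self.grade!r}")

    @property
    def subtype(self) -> str | None:
        """HR/HER2 subtype derived from er, pr and her2 when all known."""
        if None in (self.er, self.pr, self.her2):
            return None
        hr = "HR+" if "positive" in (self.er, self.pr) else "HR-"
        h2 = "HER2+" if self.her2 == "positive" else "HER2-"
        return hr + h2


@dataclass
class SlideCellMap:
    """All cells of one patient slide plus compartment geometry.

    ``cells`` has one row per cell with the mandatory columns and one 0/1
    column per marker; unknown input columns are preserved untouched.
    """

    patient_id: str
    cells: pd.DataFrame
    geometry: CompartmentGeometry
    allow_ki67_in_mif: bool = False

    def __post_init__(self) -> None:
        self.cells = validate_cell_table(self.cells, allow_ki67_in_mif=self.allow_ki67_in_mif)

    @property
    def assay_set(self) -> set[str]:
        return set(self.cells["assay"].unique())

    def subset_cells(self, assay: str | None = None) -> pd.DataFrame:
        if assay is None:
            return self.cells
        return self.cells[self.cells["assay"] == assay]


def validate_cell_table(df: pd.DataFrame, allow_ki67_in_mif: bool = False) -> pd.DataFrame:
    """Validate schema; returns the table with marker columns as uint8."""
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    df = df.copy()
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise SchemaError(f"duplicate cell_id {dup!r}")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            row = int(np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0])
            raise SchemaError(f"non-finite coordinate in column {col!r}, row {row}")
        df[col] = vals.astype(float)
    bad_assay = ~df["assay"].isin(ASSAYS)
    if bad_assay.any():
        row = int(np.flatnonzero(bad_assay.to_numpy())[0])
        raise SchemaError(f"unknown assay {df['assay'].iloc[row]!r} in row {row}")
    bad_comp = ~df["compartment"].isin(COMPARTMENTS)
    if bad_comp.any():
        row = int(np.flatnonzero(bad_comp.to_numpy())[0])
        raise SchemaError(f"unknown compartment {df['compartment'].iloc[row]!r} in row {row}")
    for marker in MARKERS:
        if marker not in df.columns:
            df[marker] = 0
        vals = pd.to_numeric(df[marker], errors="coerce").to_numpy(dtype=float)
        ok = np.isin(vals, (0.0, 1.0))
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise SchemaError(
                f"non-binary marker value {df[marker].iloc[row]!r} in column {marker!r}, row {row}"
            )
        df[marker] = vals.astype(np.uint8)
    if not allow_ki67_in_mif:
        bad = (df["assay"] == "mif") & (df["Ki67"] == 1)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"Ki67 positivity on mIF assay in row {row} (not in the panel)")
    return df


# ---------------------------------------------------------------------------
# compartment assignment

def assign_compartments(
    cells: pd.DataFrame,
    geometry: CompartmentGeometry,
    force: bool = False,
) -> pd.DataFrame:
    """Label cells by point-in-polygon test against the compartment geometry.

    Boundary points are resolved by precedence epithelium > debris > stroma
    > background (closed polygons; ``covers`` semantics). When the input
    already carries compartment labels they are kept unless ``force``.
    Points inside no polygon get "background". Idempotent.
    """
    out = cells.copy()
    has_labels = "compartment" in out.columns and out["compartment"].notna().all() and (
        out["compartment"].isin(COMPARTMENTS).all() if len(out) else True
    )
    if has_labels and not force:
        return out
    pts = shapely.points(out["x_um"].to_numpy(float), out["y_um"].to_numpy(float))
    labels = np.full(len(out), "background", dtype=object)
    unassigned = np.ones(len(out), dtype=bool)
    for name in COMPARTMENT_PRECEDENCE:
        geom = geometry.polygons.get(name)
        if geom is None or geom.is_empty or not unassigned.any():
            continue
        if not geom.is_valid:
            raise GeometryError(f"invalid polygon for {name!r}")
        hit = shapely.covers(geom, pts[unassigned])
        idx = np.flatnonzero(unassigned)[hit]
        labels[idx] = name
        unassigned[idx] = False
    out["compartment"] = labels
    return out


# ---------------------------------------------------------------------------
# file I/O

def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cols = list(MANDATORY_COLUMNS[:4]) + list(MARKERS) + ["compartment"]
    extra = [c for c in cells.columns if c not in cols]
    cells.to_csv(path, index=False, columns=cols + extra)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df


def write_geometry(geometry: CompartmentGeometry, path: str | Path) -> None:
    features = []
    for name, geom in geometry.polygons.items():
        features.append(
            {
                "type": "Feature",
                "properties": {"compartment": name},
                "geometry": geom_mapping(geom),
            }
        )
    payload = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"area_mm2": geometry.area_mm2, "units": "um"},
    }
    Path(path).write_text(json.dumps(payload))


def read_geometry(path: str | Path) -> CompartmentGeometry:
    payload = json.loads(Path(path).read_text())
    polygons: dict[str, BaseGeometry] = {}
    for feat in payload.get("features", []):
        name = feat.get("properties", {}).get("compartment")
        if name is None:
            raise GeometryError("geometry feature without 'compartment' property")
        geom = geom_shape(feat["geometry"])
        polygons[name] = polygons[name].union(geom) if name in polygons else geom
    area = {k: float(v) for k, v in payload.get("properties", {}).get("area_mm2", {}).items()}
    return CompartmentGeometry(polygons=polygons, area_mm2=area)


def read_slide(
    cell_csv_path: str | Path,
    geometry_path: str | Path,
    patient_id: str | None = None,
    force_reassign: bool = False,
) -> SlideCellMap:
    """Read and validate a slide from its cell CSV and GeoJSON geometry."""
    cells = read_cell_table(cell_csv_path)
    geometry = read_geometry(geometry_path)
    if "compartment" not in cells.columns or force_reassign:
        cells = assign_compartments(cells, geometry, force=True)
    if patient_id is None:
        patient_id = Path(cell_csv_path).stem
    return SlideCellMap(patient_id=patient_id, cells=cells, geometry=geometry)


def write_slide(slide: SlideCellMap, cell_csv_path: str | Path, geometry_path: str | Path) -> None:
    write_cell_table(slide.cells, cell_csv_path)
    write_geometry(slide.geometry, geometry_path)


def write_metadata(metadata: Iterable[PatientMetadata], path: str | Path) -> None:
    rows = []
    for md in metadata:
        row = dataclasses.asdict(md)
        row["subtype"] = md.subtype
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[PatientMetadata]:
    df = pd.read_csv(path)
    fields = {f.name for f in dataclasses.fields(PatientMetadata)}
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for key in fields:
            if key not in row or pd.isna(row[key]):
                continue
            val = row[key]
            if key == "grade":
                val = int(val)
            if key == "foxp3_assessable":
                val = bool(val)
            kwargs[key] = val
        out.append(PatientMetadata(**kwargs))
    return out
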