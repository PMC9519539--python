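import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from dcisime import SlideCellMap, SlideSpec, generate_slide
from dcisime.io import CompartmentGeometry
from shapely.geometry import box

DEFAULT_INTENSITY = {
    "b_cell": 100.0,
    "t_helper": 150.0,
    "t_cytotoxic": 80.0,
    "t_reg": 40.0,
    "macrophage": 60.0,
}


@pytest.fixture
def small_spec():
    return SlideSpec(
        slide_width_um=2000.0,
        slide_height_um=2000.0,
        n_ducts=2,
        duct_radius_um=(120.0, 200.0),
        stroma_band_um=120.0,
        epithelial_cell_density=2000.0,
        stromal_intensity=dict(DEFAULT_INTENSITY, activated_cytotoxic=30.0),
        intraepithelial_intensity={"t_cytotoxic": 20.0, "t_reg": 10.0},
        seed=7,
    )


@pytest.fixture
def small_slide(small_spec):
    return generate_slide(small_spec, patient_id="T1")


def make_manual_slide(rows, areas=None, patient_id="M1"):
    """Slide from explicit cell rows; geometry carries areas only."""
    defaults = {
        "assay": "mif",
        "panCK": 0, "CD3": 0, "CD8": 0, "CD20": 0, "FOXP3": 0, "CD68": 0, "Ki67": 0,
        "compartment": "stroma",
        "x_um": 0.0, "y_um": 0.0,
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("cell_id", f"{patient_id}-{i}")
        records.append(rec)
    cells = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["cell_id", *defaults.keys()]
    )
    geometry = CompartmentGeometry(area_mm2=dict(areas or {"stroma": 1.0, "epithelium": 1.0}))
    return SlideCellMap(patient_id=patient_id, cells=cells, geometry=geometry)


@pytest.fixture
def manual_slide_factory():
    return make_manual_slide


@pytest.fixture
def square_geometry():
    """100×100 µm epithelium square inside a 300×300 µm slide with a
    stroma frame around it."""
    epi = box(100, 100, 200, 200)
    slide = box(0, 0, 300, 300)
    stroma = slide.difference(epi)
    return CompartmentGeometry(polygons={"epithelium": epi, "stroma": stroma})


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
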