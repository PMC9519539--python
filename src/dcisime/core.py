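"""Shared vocabularies, unit helpers and error types."""

from __future__ import annotations

#: Marker panel. Ki67 comes from the separate double-IHC assay; the six
#: others form the mIF panel.
MARKERS: tuple[str, ...] = ("panCK", "CD3", "CD8", "CD20", "FOXP3", "CD68", "Ki67")

MIF_MARKERS: tuple[str, ...] = ("panCK", "CD3", "CD8", "CD20", "FOXP3", "CD68")

#: Tissue compartments from segmentation. Only epithelium and stroma are
#: analysed; debris and background are excluded from every metric.
COMPARTMENTS: tuple[str, ...] = ("epithelium", "stroma", "debris", "background")
ANALYSED_COMPARTMENTS: tuple[str, ...] = ("stroma", "epithelium")

ASSAYS: tuple[str, ...] = ("mif", "cd8ki67")

#: Per-cell phenotype labels produced by gating.
PHENOTYPES: tuple[str, ...] = (
    "dcis_cell",
    "b_cell",
    "t_helper",
    "t_cytotoxic",
    "t_reg",
    "macrophage",
    "activated_cytotoxic",
    "other",
)

#: The eight immune categories used for densities and pairwise ratios,
#: in canonical order (ratio numerators come earlier in this tuple).
SUBSETS: tuple[str, ...] = (
    "lymphocytes",
    "t_all",
    "b_cell",
    "t_helper",
    "t_cytotoxic",
    "t_reg",
    "macrophage",
    "activated_cytotoxic",
)

#: Subsets whose definition depends on FOXP3 gating.
FOXP3_DEPENDENT_SUBSETS: tuple[str, ...] = ("lymphocytes", "t_helper", "t_reg")

UM2_PER_MM2 = 1_000_000.0


def um2_to_mm2(area_um2: float) -> float:
    """Convert an area in square micrometres to square millimetres."""
    return area_um2 / UM2_PER_MM2


def image_field_area_mm2(width_um: float, height_um: float) -> float:
    """Area of a rectangular image field given its side lengths in µm."""
    if width_um <= 0 or height_um <= 0:
        raise ValueError("field dimensions must be positive")
    return um2_to_mm2(width_um * height_um)


class SchemaError(ValueError):
    """A cell table or geometry file violates the expected schema."""


class GeometryError(ValueError):
    """Compartment geometry is invalid (e.g. self-intersecting polygon)."""


class VocabularyError(KeyError):
    """A marker, compartment or subset identifier is outside the fixed vocabulary."""


class PlacementError(RuntimeError):
    """Rejection sampling failed to place geometry within the attempt bound."""


class ConsistencyError(ValueError):
    """Mutually inconsistent inputs (e.g. cells counted in a zero-area compartment)."""
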