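"""Synthetic DCIS slide and cohort generator.

Slides are point patterns on a rectangle: ducts are disks of epithelium,
each wrapped in an annulus of periductal stroma; everything else is
background. Epithelial cells and each immune subset are homogeneous
Poisson within their compartment (optionally thinned toward duct
boundaries), TLS-like follicles are seeded as B-cell blobs with a T-cell
ring, and a separate CD8/Ki67 double-stain point pattern is emitted for
the same tissue. Everything is driven by one root seed; cohorts derive
per-slide child seeds through ``numpy.random.SeedSequence.spawn`` so the
output is reproducible and independent of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .core import MARKERS, PlacementError, um2_to_mm2
from .io import CompartmentGeometry, PatientMetadata, SlideCellMap, assign_compartments

#: Generative phenotypes accepted in intensity maps. "activated_cytotoxic"
#: and "cd8_resting" live on the double-IHC assay; the rest on mIF.
GENERATIVE_PHENOTYPES = (
    "b_cell",
    "t_helper",
    "t_cytotoxic",
    "t_reg",
    "macrophage",
    "other",
    "activated_cytotoxic",
    "cd8_resting",
)

_PLACEMENT_ATTEMPTS_PER_DUCT = 500


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide; ``seed`` fixes it byte-for-byte."""

    slide_width_um: float = 4000.0
    slide_height_um: float = 4000.0
    n_ducts: int = 4
    duct_radius_um: tuple[float, float] = (150.0, 300.0)
    stroma_band_um: float = 150.0
    epithelial_cell_density: float = 3000.0  # cells/mm² inside ducts
    stromal_intensity: dict[str, float] = field(default_factory=dict)
    intraepithelial_intensity: dict[str, float] = field(default_factory=dict)
    boundary_decay_um: float | None = None
    n_tls: int = 0
    tls_b_cells: int = 60
    tls_t_ring_cells: int = 80
    tls_follicle_radius_um: float = 40.0
    tls_ring_width_um: float = 30.0
    n_gc_tls: int = 0
    gc_cells: int = 80
    gc_core_ki67_fraction: float = 0.7
    treg_cd8_fraction: float = 0.0
    flip_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.duct_radius_um
        if lo > hi or lo <= 0:
            raise ValueError("duct_radius_um must satisfy 0 < min <= max")
        if self.slide_width_um <= 0 or self.slide_height_um <= 0:
            raise ValueError("slide dimensions must be positive")
        for intensity in (self.stromal_intensity, self.intraepithelial_intensity):
            for key, lam in intensity.items():
                if key not in GENERATIVE_PHENOTYPES:
                    raise ValueError(f"unknown generative phenotype {key!r}")
                if lam < 0:
                    raise ValueError(f"negative intensity for {key!r}")
        if not 0 <= self.flip_noise <= 1:
            raise ValueError("flip_noise must be in [0, 1]")
        if not 0 <= self.treg_cd8_fraction <= 1:
            raise ValueError("treg_cd8_fraction must be in [0, 1]")

    def scaled(self, factor: Mapping[str, float] | float, compartments=("stroma", "epithelium")) -> "SlideSpec":
        """Return a copy with intensities multiplied (per-subset map or scalar)."""
        new = dataclasses.replace(self)
        new.stromal_intensity = dict(self.stromal_intensity)
        new.intraepithelial_intensity = dict(self.intraepithelial_intensity)
        for comp, intensity in (
            ("stroma", new.stromal_intensity),
            ("epithelium", new.intraepithelial_intensity),
        ):
            if comp not in compartments:
                continue
            for key in intensity:
                f = factor.get(key, 1.0) if isinstance(factor, Mapping) else factor
                intensity[key] = intensity[key] * f
        return new

    @classmethod
    def from_dict(cls, d: Mapping) -> "SlideSpec":
        d = dict(d)
        if "duct_radius_um" in d:
            d["duct_radius_um"] = tuple(d["duct_radius_um"])
        return cls(**d)


@dataclass
class CohortSpec:
    """A case/control cohort built from a template slide spec."""

    n_cases: int = 5
    n_controls: int = 5
    slide_spec: SlideSpec = field(default_factory=SlideSpec)
    patient_sd_log: float = 0.0
    case_effect: dict[str, float] = field(default_factory=dict)
    metadata_model: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        for key, f in self.case_effect.items():
            if f <= 0:
                raise ValueError(f"case_effect[{key!r}] must be > 0")
        if self.patient_sd_log < 0:
            raise ValueError("patient_sd_log must be >= 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if "slide_spec" in d:
            d["slide_spec"] = SlideSpec.from_dict(d["slide_spec"])
        return cls(**d)


@dataclass
class RaterSimSpec:
    """Two-way random-effects rater model: y_ij = mu + a_i + b_j + e_ij."""

    n_subjects: int = 100
    n_raters: int = 2
    true_icc: float = 0.8
    subject_sd: float | None = None
    rater_sd: float | None = None
    error_sd: float | None = None
    unit: str = "single"  # which ICC unit true_icc refers to: single | mean-of-k
    mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.true_icc < 1:
            raise ValueError("true_icc must be in [0, 1)")
        if self.unit not in ("single", "mean-of-k"):
            raise ValueError("unit must be 'single' or 'mean-of-k'")
        if self.subject_sd is None and self.rater_sd is None and self.error_sd is None:
            # derive a canonical decomposition: no rater effect, unit total
            self.rater_sd = 0.0
            if self.unit == "single":
                self.subject_sd = float(np.sqrt(self.true_icc))
                self.error_sd = float(np.sqrt(1.0 - self.true_icc))
            else:
                # icc_k = s2 / (s2 + e2/k) with s2 + e2 = 1
                k = self.n_raters
                icc = self.true_icc
                s2 = icc / (k - icc * (k - 1)) if icc < 1 else 1.0
                self.subject_sd = float(np.sqrt(s2))
                self.error_sd = float(np.sqrt(1.0 - s2))
        for name in ("subject_sd", "rater_sd", "error_sd"):
            val = getattr(self, name)
            if val is None or val < 0:
                raise ValueError(f"{name} must be supplied and non-negative")
        if abs(self.implied_icc() - self.true_icc) > 1e-9:
            raise ValueError(
                f"variance components imply ICC {self.implied_icc():.6g}, "
                f"not the requested true_icc {self.true_icc:.6g}"
            )

    def implied_icc(self) -> float:
        s2 = self.subject_sd**2
        r2 = self.rater_sd**2
        e2 = self.error_sd**2
        tot = s2 + r2 + e2
        if tot == 0:
            return 0.0
        if self.unit == "single":
            return s2 / tot
        return s2 / (s2 + (r2 + e2) / self.n_raters)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RaterSimSpec":
        return cls(**dict(d))


# ---------------------------------------------------------------------------
# geometry construction

def _place_ducts(spec: SlideSpec, rng: np.random.Generator):
    """Non-overlapping disks fully inside the slide, largest first."""
    lo, hi = spec.duct_radius_um
    radii = np.sort(rng.uniform(lo, hi, spec.n_ducts))[::-1]
    centers: list[tuple[float, float]] = []
    placed: list[float] = []
    max_attempts = _PLACEMENT_ATTEMPTS_PER_DUCT * max(spec.n_ducts, 1)
    attempts = 0
    for r in radii:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place {spec.n_ducts} non-overlapping ducts "
                    f"within {max_attempts} attempts"
                )
            x = rng.uniform(r, spec.slide_width_um - r)
            y = rng.uniform(r, spec.slide_height_um - r)
            ok = all(
                (x - cx) ** 2 + (y - cy) ** 2 > (r + cr) ** 2
                for (cx, cy), cr in zip(centers, placed)
            )
            if ok:
                centers.append((x, y))
                placed.append(float(r))
                break
    return np.asarray(centers, float).reshape(-1, 2), np.asarray(placed, float)


def build_geometry(spec: SlideSpec, rng: np.random.Generator):
    """Construct compartment polygons; returns (geometry, centers, radii)."""
    slide = box(0, 0, spec.slide_width_um, spec.slide_height_um)
    centers, radii = _place_ducts(spec, rng)
    disks = [Point(c).buffer(r, quad_segs=64) for c, r in zip(centers, radii)]
    epithelium = unary_union(disks) if disks else Point(0, 0).buffer(0)
    rings = [Point(c).buffer(r + spec.stroma_band_um, quad_segs=64) for c, r in zip(centers, radii)]
    stroma = (unary_union(rings).difference(epithelium)).intersection(slide) if rings else epithelium.buffer(0)
    background = slide.difference(epithelium).difference(stroma)
    geometry = CompartmentGeometry(
        polygons={"epithelium": epithelium, "stroma": stroma, "background": background}
    )
    return geometry, centers, radii


def _sample_uniform_in(geom, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a shapely geometry by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    frac = max(geom.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    out = []
    remaining = n
    while remaining > 0:
        m = int(remaining / frac * 1.5) + 16
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(geom, xs, ys)
        pts = np.column_stack([xs[keep], ys[keep]])[:remaining]
        out.append(pts)
        remaining -= len(pts)
    return np.concatenate(out)


def _markers_for_phenotype(phen: str, n: int, rng: np.random.Generator, treg_cd8_fraction: float) -> pd.DataFrame:
    flags = pd.DataFrame(0, index=range(n), columns=list(MARKERS), dtype=np.uint8)
    if phen == "b_cell":
        flags["CD20"] = 1
    elif phen == "t_helper":
        flags["CD3"] = 1
    elif phen == "t_cytotoxic":
        flags["CD3"] = 1
        flags["CD8"] = 1
    elif phen == "t_reg":
        flags["CD3"] = 1
        flags["FOXP3"] = 1
        if treg_cd8_fraction > 0:
            flags["CD8"] = (rng.random(n) < treg_cd8_fraction).astype(np.uint8)
    elif phen == "macrophage":
        flags["CD68"] = 1
    elif phen == "activated_cytotoxic":
        flags["CD8"] = 1
        flags["Ki67"] = 1
    elif phen == "cd8_resting":
        flags["CD8"] = 1
    return flags


def generate_slide(spec: SlideSpec, patient_id: str = "synthetic") -> SlideCellMap:
    """Generate one slide; deterministic given ``spec`` (including seed)."""
    rng = np.random.default_rng(spec.seed)
    geometry, centers, radii = build_geometry(spec, rng)
    epithelium = geometry.polygons["epithelium"]
    stroma = geometry.polygons["stroma"]

    frames: list[pd.DataFrame] = []

    def emit(points: np.ndarray, phen: str, assay: str, compartment: str | None) -> None:
        n = len(points)
        if n == 0:
            return
        flags = _markers_for_phenotype(phen, n, rng, spec.treg_cd8_fraction)
        df = pd.DataFrame({"x_um": points[:, 0], "y_um": points[:, 1]})
        df["assay"] = assay
        df = pd.concat([df, flags], axis=1)
        df["true_phenotype"] = phen
        df["compartment"] = compartment if compartment is not None else pd.NA
        frames.append(df)

    # epithelial (DCIS) cells — mIF assay, panCK+
    n_epi = rng.poisson(spec.epithelial_cell_density * geometry.area("epithelium"))
    if n_epi:
        pts = _sample_uniform_in(epithelium, n_epi, rng)
        flags = pd.DataFrame(0, index=range(n_epi), columns=list(MARKERS), dtype=np.uint8)
        flags["panCK"] = 1
        df = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
        df["assay"] = "mif"
        df = pd.concat([df, flags], axis=1)
        df["true_phenotype"] = "dcis_cell"
        df["compartment"] = "epithelium"
        frames.append(df)

    # immune cells per compartment × generative phenotype (fixed order)
    for comp, geom, intensity in (
        ("stroma", stroma, spec.stromal_intensity),
        ("epithelium", epithelium, spec.intraepithelial_intensity),
    ):
        area = geometry.area(comp)
        for phen in GENERATIVE_PHENOTYPES:
            lam = intensity.get(phen, 0.0)
            if lam == 0.0 or area == 0.0:
                continue
            n = rng.poisson(lam * area)
            if n == 0:
                continue
            pts = _sample_uniform_in(geom, n, rng)
            if comp == "stroma" and spec.boundary_decay_um:
                # weighted re-draw toward the duct boundary, count preserved:
                # oversample candidates, keep n by Gumbel-top-k weighted choice
                cand = _sample_uniform_in(geom, max(8 * n, 64), rng)
                d = shapely.distance(shapely.points(cand[:, 0], cand[:, 1]), epithelium)
                keys = np.log(np.exp(-d / spec.boundary_decay_um) + 1e-300) + rng.gumbel(size=len(cand))
                pts = cand[np.argsort(keys)[::-1][:n]]
            assay = "cd8ki67" if phen in ("activated_cytotoxic", "cd8_resting") else "mif"
            emit(pts, phen, assay, comp)

    # seeded zone-TLS follicles (mIF): B-cell blob + surrounding T ring
    for _ in range(spec.n_tls):
        center = _tls_center(stroma, epithelium, spec, rng)
        b_pts = _points_in_disk(center, spec.tls_follicle_radius_um, spec.tls_b_cells, rng)
        t_pts = _points_in_annulus(
            center,
            spec.tls_follicle_radius_um,
            spec.tls_follicle_radius_um + spec.tls_ring_width_um,
            spec.tls_t_ring_cells,
            rng,
        )
        emit(b_pts, "b_cell", "mif", None)
        emit(t_pts, "t_helper", "mif", None)

    # seeded GC aggregates (cd8ki67): Ki67+ core + CD8+ mantle
    for _ in range(spec.n_gc_tls):
        center = _tls_center(stroma, epithelium, spec, rng)
        r = spec.tls_follicle_radius_um
        n_core = spec.gc_cells // 2
        n_mantle = spec.gc_cells - n_core
        core = _points_in_disk(center, r * np.sqrt(0.5), n_core, rng)
        mantle = _points_in_annulus(center, r * np.sqrt(0.5), r, n_mantle, rng)
        n_pos = int(round(spec.gc_core_ki67_fraction * n_core))
        emit(core[:n_pos], "activated_cytotoxic", "cd8ki67", None)  # Ki67+ core
        emit(core[n_pos:], "cd8_resting", "cd8ki67", None)
        emit(mantle, "cd8_resting", "cd8ki67", None)

    if frames:
        cells = pd.concat(frames, ignore_index=True)
    else:
        cells = pd.DataFrame(
            columns=["x_um", "y_um", "assay", *MARKERS, "true_phenotype", "compartment"]
        )

    # flip noise to exercise gating conflict rules (mIF markers only)
    if spec.flip_noise > 0 and len(cells):
        for marker in MARKERS:
            flip = rng.random(len(cells)) < spec.flip_noise
            col = cells[marker].to_numpy(np.uint8)
            cells[marker] = np.where(flip, 1 - col, col).astype(np.uint8)
        cells.loc[cells["assay"] == "mif", "Ki67"] = 0

    cells.insert(0, "cell_id", [f"{patient_id}-{i}" for i in range(len(cells))])
    # geometry-consistent labels for TLS cells (others carry their compartment)
    missing = cells["compartment"].isna()
    if missing.any():
        labelled = assign_compartments(cells.loc[missing], geometry, force=True)
        cells.loc[missing, "compartment"] = labelled["compartment"].to_numpy()
    return SlideCellMap(patient_id=patient_id, cells=cells, geometry=geometry)


def _tls_center(stroma, epithelium, spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    """A stromal point, preferring clearance for the full follicle + ring."""
    want = spec.tls_follicle_radius_um + spec.tls_ring_width_um
    best = None
    for _ in range(64):
        pt = _sample_uniform_in(stroma, 1, rng)[0]
        d = Point(pt).distance(epithelium)
        if d >= want:
            return pt
        if best is None or d > best[1]:
            best = (pt, d)
    return best[0]


def _points_in_disk(center: np.ndarray, radius: float, n: int, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.random(n))
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


def _points_in_annulus(center: np.ndarray, r0: float, r1: float, n: int, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi, n)
    r = np.sqrt(rng.uniform(r0**2, r1**2, n))
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])


# ---------------------------------------------------------------------------
# cohorts

_DEFAULT_METADATA_MODEL: dict[str, dict] = {
    "grade": {1: 0.12, 2: 0.65, 3: 0.23},
    "er": {"negative": 0.20, "positive": 0.80},
    "pr": {"negative": 0.37, "positive": 0.63},
    "her2": {"negative": 0.71, "positive": 0.29},
    "cox2": {"low": 0.09, "high": 0.91},
    "ki67_category": {"<14%": 0.74, ">=14%": 0.11, "NA": 0.15},
    "fibrosis": {"absent": 0.70, "present": 0.30},
    "comedonecrosis": {"absent": 0.21, "present": 0.79},
}


def _draw_categorical(model: Mapping, rng: np.random.Generator):
    keys = list(model.keys())
    probs = np.asarray([model[k] for k in keys], float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def generate_cohort(spec: CohortSpec) -> list[tuple[SlideCellMap, PatientMetadata]]:
    """Generate ``n_cases + n_controls`` slides with patient metadata.

    Case slides have stromal intensities multiplied by ``case_effect``;
    per-patient lognormal multipliers apply identically to both
    compartments. Child seeds come from SeedSequence.spawn in patient
    order (cases first), so any one patient is reproducible in isolation.
    """
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_cases + spec.n_controls
    children = root.spawn(n_total)
    model = {**_DEFAULT_METADATA_MODEL, **spec.metadata_model}
    out = []
    for i in range(n_total):
        is_case = i < spec.n_cases
        pid = f"P{i:03d}"
        child = children[i]
        meta_rng = np.random.default_rng(child)
        mult = float(np.exp(meta_rng.normal(0.0, spec.patient_sd_log))) if spec.patient_sd_log else 1.0
        slide_spec = spec.slide_spec.scaled(mult)
        if is_case and spec.case_effect:
            slide_spec = slide_spec.scaled(spec.case_effect, compartments=("stroma",))
        slide_spec.seed = int(child.generate_state(1)[0])
        slide = generate_slide(slide_spec, patient_id=pid)
        md = PatientMetadata(
            patient_id=pid,
            outcome="case" if is_case else "control",
            grade=int(_draw_categorical(model["grade"], meta_rng)),
            er=_draw_categorical(model["er"], meta_rng),
            pr=_draw_categorical(model["pr"], meta_rng),
            her2=_draw_categorical(model["her2"], meta_rng),
            cox2=_draw_categorical(model["cox2"], meta_rng),
            ki67_category=_draw_categorical(model["ki67_category"], meta_rng),
            fibrosis=_draw_categorical(model["fibrosis"], meta_rng),
            comedonecrosis=_draw_categorical(model["comedonecrosis"], meta_rng),
        )
        out.append((slide, md))
    return out


# ---------------------------------------------------------------------------
# rater simulation

def simulate_rater_scores(spec: RaterSimSpec) -> np.ndarray:
    """Draw an n_subjects × n_raters matrix from the two-way random model."""
    rng = np.random.default_rng(spec.seed)
    a = rng.normal(0.0, spec.subject_sd, (spec.n_subjects, 1))
    b = rng.normal(0.0, spec.rater_sd, (1, spec.n_raters))
    e = rng.normal(0.0, spec.error_sd, (spec.n_subjects, spec.n_raters))
    return spec.mean + a + b + e
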