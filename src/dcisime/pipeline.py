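"""End-to-end pipeline driver: read a YAML config, run the requested
analysis stages over a cohort of slides, and write tidy CSV tables plus
a run log (versions, seed, config hash). Partial results are flushed as
each stage completes."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SUBSETS
from .io import PatientMetadata, SlideCellMap, read_metadata, read_slide, write_metadata
from .spatial import compute_densities, compute_ratios, proximity_table
from .stats import contrast_suite
from .tls import TLSParams, detect_gc_tls, detect_zone_tls, records_to_frame, tls_density

FLOAT_FORMAT = "%.10g"


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(
    config_path: str | Path | None = None,
    config: dict | None = None,
    slides: list[SlideCellMap] | None = None,
    metadata: list[PatientMetadata] | None = None,
) -> dict[str, Path]:
    """Run the configured stages; returns a map of table name -> path.

    Either a YAML config path or a config dict must be given. Slides and
    metadata may be passed in memory (e.g. freshly simulated); otherwise
    they are loaded from the paths listed in the config.
    """
    if config is None:
        if config_path is None:
            raise ValueError("need config_path or config")
        config = yaml.safe_load(Path(config_path).read_text())
    out_dir = Path(config.get("output_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    switches = config.get("analyses", {})
    params = config.get("params", {})
    seed = int(config.get("seed", 0))
    mode = params.get("formula_mode", "strict-literal")
    outputs: dict[str, Path] = {}

    if slides is None:
        slides = []
        for entry in config.get("slides", []):
            slides.append(
                read_slide(entry["cells"], entry["geometry"], patient_id=entry.get("patient_id"))
            )
    if metadata is None:
        md_path = config.get("metadata")
        metadata = read_metadata(md_path) if md_path else []

    md_by_id = {m.patient_id: m for m in metadata}
    if metadata:
        path = out_dir / "metadata.csv"
        write_metadata(metadata, path)
        outputs["metadata"] = path

    log = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "dcisime_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_slides": len(slides),
        "stages": [],
    }

    def flush_log():
        path = out_dir / "log.json"
        path.write_text(json.dumps(log, indent=2, sort_keys=True))
        outputs["log"] = path

    def stage(name, fn):
        try:
            fn()
        except Exception as exc:  # annotate with stage context, keep partials
            flush_log()
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log["stages"].append(name)

    density_frames: list[pd.DataFrame] = []

    def run_densities():
        for slide in slides:
            md = md_by_id.get(slide.patient_id)
            assessable = md.foxp3_assessable if md else True
            try:
                density_frames.append(
                    compute_densities(slide, mode=mode, foxp3_assessable=assessable)
                )
            except Exception as exc:
                raise RuntimeError(f"patient {slide.patient_id}: {exc}") from exc
        df = pd.concat(density_frames, ignore_index=True) if density_frames else pd.DataFrame()
        path = out_dir / "densities.csv"
        _write(df, path)
        outputs["densities"] = path

    need_density = switches.get("densities") or switches.get("ratios") or switches.get("stats")
    if need_density:
        stage("densities", run_densities)

    if switches.get("ratios"):
        def run_ratios():
            df = pd.concat(density_frames, ignore_index=True)
            ratios = compute_ratios(df)
            path = out_dir / "ratios.csv"
            _write(ratios, path)
            outputs["ratios"] = path
        stage("ratios", run_ratios)

    if switches.get("proximity"):
        def run_proximity():
            radius = float(params.get("proximity_radius_um", 25.0))
            frames = []
            for slide in slides:
                try:
                    frames.append(proximity_table(slide, radius_um=radius, mode=mode))
                except Exception as exc:
                    raise RuntimeError(f"patient {slide.patient_id}: {exc}") from exc
            path = out_dir / "proximity.csv"
            _write(pd.concat(frames, ignore_index=True), path)
            outputs["proximity"] = path
        stage("proximity", run_proximity)

    if switches.get("tls"):
        def run_tls():
            tls_params = TLSParams(**params.get("tls", {}))
            rec_frames, dens_rows = [], []
            for slide in slides:
                zone = detect_zone_tls(slide, tls_params)
                gc = detect_gc_tls(slide, tls_params)
                frame = records_to_frame(zone + gc)
                frame.insert(0, "patient_id", slide.patient_id)
                rec_frames.append(frame)
                area = slide.geometry.area("stroma") + slide.geometry.area("epithelium")
                if area > 0:
                    dens_rows.append(tls_density(zone, area, "zone", slide.patient_id))
                    dens_rows.append(tls_density(gc, area, "gc", slide.patient_id))
            path = out_dir / "tls.csv"
            _write(pd.concat(rec_frames, ignore_index=True), path)
            outputs["tls"] = path
            path = out_dir / "tls_density.csv"
            _write(pd.DataFrame(dens_rows), path)
            outputs["tls_density"] = path
        stage("tls", run_tls)

    if switches.get("stats") and metadata:
        def run_stats():
            dens = pd.concat(density_frames, ignore_index=True)
            feats = []
            for comp in ("stroma", "epithelium"):
                sub = dens[dens["compartment"] == comp]
                feats.append(
                    pd.DataFrame(
                        {
                            "patient_id": sub["patient_id"],
                            "family": f"{comp}_densities",
                            "feature_id": sub["subset_id"] + "_" + comp,
                            "value": sub["density_cells_per_mm2"],
                        }
                    )
                )
            if "ratios" in outputs:
                ratios = pd.read_csv(outputs["ratios"])
                for comp in ("stroma", "epithelium"):
                    sub = ratios[ratios["compartment"] == comp]
                    feats.append(
                        pd.DataFrame(
                            {
                                "patient_id": sub["patient_id"],
                                "family": f"{comp}_ratios",
                                "feature_id": sub["numerator_subset"]
                                + "_over_"
                                + sub["denominator_subset"]
                                + "_"
                                + comp,
                                "value": sub["ratio"],
                            }
                        )
                    )
            if "proximity" in outputs:
                prox = pd.read_csv(outputs["proximity"])
                feats.append(
                    pd.DataFrame(
                        {
                            "patient_id": prox["patient_id"],
                            "family": "proximity",
                            "feature_id": prox["subset_id"] + "_proximity",
                            "value": prox["proximity_index"],
                        }
                    )
                )
            if "tls_density" in outputs:
                tlsd = pd.read_csv(outputs["tls_density"])
                feats.append(
                    pd.DataFrame(
                        {
                            "patient_id": tlsd["patient_id"],
                            "family": "tls",
                            "feature_id": tlsd["tls_type"] + "_tls_density",
                            "value": tlsd["density_per_mm2"],
                        }
                    )
                )
            features = pd.concat(feats, ignore_index=True)
            md_df = pd.read_csv(outputs["metadata"])
            res = contrast_suite(
                features,
                md_df,
                n_perm=int(params.get("n_perm", 2000)),
                seed=seed,
                stratum_query=params.get("stratum_query"),
                include_clinicopath=bool(params.get("clinicopath", True)),
            )
            path = out_dir / "stats.csv"
            _write(res, path)
            outputs["stats"] = path
        stage("stats", run_stats)

    flush_log()
    return outputs
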