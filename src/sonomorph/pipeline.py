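"""Orchestration: simulate -> synthesize -> quantify -> differential expression.

A single run is driven by a nested configuration dictionary (YAML on disk),
an explicit seed, and an output directory.  Every stochastic stage derives
its own sub-seed from the run seed, all parameters are echoed into the run
manifest, and the report tables are byte-reproducible given (config, seed).
"""

from __future__ import annotations

import copy
import json
import datetime
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, chamber, morphometrics, recovery, synth
from .exceptions import ConfigError
from .proteomics import DifferentialExpression, pca_scores

__all__ = ["default_config", "load_config", "dump_config", "run_pipeline"]


def default_config() -> dict[str, Any]:
    """A compact, desk-scale run configuration."""
    return {
        "geometry": "rings",  # rings | honeycomb | random
        "mode": {"m": 0, "n": 4, "chamber_dim": 21.0, "grid_resolution": 512},
        "image": {
            "image_size": 1024,
            "pixel_pitch": 5.0,
            "background_fraction": 0.05,
            "enhancement_pct": 438.0,
            "line_width": 100.0,
            "noise_sd": 0.0,
        },
        "network": {
            "days": [1, 3, 5],
            "image_size": 384,
            "pixel_pitch": 0.5,
            "ribbon_count": 6,
        },
        "proteome": {"n_proteins": 2000, "n_up": 322, "n_down": 130},
        "de": {"alpha": 0.05},
    }


def load_config(path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = default_config()
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            base[key].update(val)
        else:
            base[key] = val
    return base


def dump_config(config: dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def _simulate_stage(config: dict[str, Any]) -> dict[str, Any]:
    geom = config["geometry"]
    m = config["mode"]
    if geom == "honeycomb":
        spec = chamber.ModeSpec("square", m=m.get("m", 5), n=m.get("n", 1),
                                chamber_dim=m.get("chamber_dim", 15.0),
                                grid_resolution=m["grid_resolution"])
        fld = chamber.square_mode_field(spec)
    else:
        spec = chamber.ModeSpec("round", m=m["m"], n=m["n"],
                                chamber_dim=m["chamber_dim"],
                                grid_resolution=m["grid_resolution"])
        fld = chamber.round_mode_field(spec)
    nodal = chamber.extract_nodal_set(fld)
    out: dict[str, Any] = {"field": fld, "nodal": nodal}
    if nodal.radii is not None:
        out["nodal_radii_mm"] = [round(r, 4) for r in nodal.radii]
    return out


def run_pipeline(config: dict[str, Any] | None = None, seed: int = 0,
                 outdir: str | Path | None = None
                 ) -> tuple[dict[str, Any], dict[str, Any]]:
    """Execute all stages; return ``(manifest, report)``.

    The report aggregates the nodal radii table, per-ring enhancement and
    FWHM, the valley-to-peak ratio, per-day thickness statistics, the
    orientation distribution summary and the differential-expression
    counts.  Pattern-specific sections are omitted for the random geometry.
    When ``outdir`` is given, report tables (CSV) and ``report.json`` /
    ``manifest.json`` are written there.
    """
    config = copy.deepcopy(config) if config else default_config()
    geom = config["geometry"]
    if geom not in ("rings", "honeycomb", "random"):
        raise ConfigError(f"unknown geometry {geom!r}")
    report: dict[str, Any] = {"geometry": geom}
    tables: dict[str, pd.DataFrame] = {}
    stage_seeds = {"pattern": seed, "control": seed + 10_000,
                   "network": seed + 20_000, "proteome": seed + 30_000}

    # --- simulate ---------------------------------------------------------
    sim = _simulate_stage(config)
    if "nodal_radii_mm" in sim:
        report["nodal_radii_mm"] = sim["nodal_radii_mm"]

    # --- synthesize + quantify images -------------------------------------
    icfg = config["image"]
    cspec = synth.ImageSpec("random", image_size=icfg["image_size"],
                            pixel_pitch=icfg["pixel_pitch"],
                            background_fraction=icfg["background_fraction"],
                            line_width=icfg["line_width"],
                            seed=stage_seeds["control"])
    control = synth.generate_random_image(cspec)

    if geom != "random":
        pspec = synth.ImageSpec(geom, image_size=icfg["image_size"],
                                pixel_pitch=icfg["pixel_pitch"],
                                background_fraction=icfg["background_fraction"],
                                enhancement_pct=icfg["enhancement_pct"],
                                line_width=icfg["line_width"],
                                noise_sd=icfg["noise_sd"],
                                seed=stage_seeds["pattern"])
        pattern = synth.generate_pattern_image(pspec, sim["field"])
        mask, seg_info = morphometrics.segment_foreground(pattern.intensity)
        report["segmentation"] = seg_info

        if geom == "rings":
            r_max = pspec.margin * (pspec.image_size - 1) / 2.0 * pspec.pixel_pitch
            prof = morphometrics.radial_profile(
                pattern.intensity.astype(float), pspec.pixel_pitch,
                dr=2 * pspec.pixel_pitch, r_max=r_max * 1.02)
            peaks = morphometrics.detect_peaks(prof, prominence=0.25)
            report["n_peaks"] = int(peaks.n_peaks)
            report["peak_radii_um"] = [round(float(p), 2)
                                       for p in peaks.peak_positions]
            vpr = morphometrics.valley_to_peak_ratio(peaks)
            report["valley_to_peak_ratio"] = (None if np.isnan(vpr)
                                              else round(vpr, 4))
            fwhm = [morphometrics.ring_fwhm(prof, peaks, i)
                    for i in range(peaks.n_peaks)]
            report["ring_fwhm_um"] = [None if np.isnan(w) else round(w, 2)
                                      for w in fwhm]
            tables["peaks"] = pd.DataFrame({
                "radius_um": peaks.peak_positions,
                "height": peaks.peak_heights,
                "fwhm_um": fwhm})

            enh = {}
            rows = []
            for ring in (0, 1):
                value = recovery.measure_ring_enhancement(pattern, control,
                                                          ring_index=ring)
                enh[f"ring{ring + 1}"] = round(value, 1)
                rows.append({"ring": ring + 1, "enhancement_pct": value})
            report["enhancement_pct"] = enh
            tables["roi_enhancement"] = pd.DataFrame(rows)

    # --- network thickness per day ----------------------------------------
    ncfg = config["network"]
    thick_rows = []
    for day in ncfg["days"]:
        nspec = synth.NetworkSpec(day=day, ribbon_count=ncfg["ribbon_count"],
                                  image_size=ncfg["image_size"],
                                  pixel_pitch=ncfg["pixel_pitch"],
                                  seed=stage_seeds["network"] + day)
        net = synth.generate_network_image(nspec)
        tmap = morphometrics.local_thickness(net.cells_mask, nspec.pixel_pitch)
        st = morphometrics.thickness_stats(tmap)
        thick_rows.append({"day": day, "mean_um": st.mean, "sd_um": st.sd,
                           "n_pixels": st.n_pixels})
    tables["thickness"] = pd.DataFrame(thick_rows)
    report["thickness_by_day"] = {
        int(r["day"]): {"mean_um": round(r["mean_um"], 2),
                        "sd_um": round(r["sd_um"], 2)}
        for r in thick_rows}

    # --- orientation -------------------------------------------------------
    src = pattern if geom != "random" else control
    filtered = morphometrics.fft_highpass(src.intensity.astype(float))
    ohist = morphometrics.orientation_distribution(filtered)
    if not ohist.empty:
        dom = float(ohist.bin_centers[int(np.argmax(ohist.weights))])
        report["dominant_orientation_deg"] = dom
        tables["orientation"] = pd.DataFrame({
            "angle_deg": ohist.bin_centers, "weight": ohist.weights})

    # --- differential expression ------------------------------------------
    pcfg = config["proteome"]
    pspec2 = synth.ProteomeSpec(n_proteins=pcfg["n_proteins"],
                                n_up=pcfg["n_up"], n_down=pcfg["n_down"],
                                seed=stage_seeds["proteome"])
    table, truth = synth.generate_proteome(pspec2)
    de = DifferentialExpression(table).fit(alpha=config["de"]["alpha"])
    report["de_counts"] = de.counts
    tables["de"] = de.frame.round(6)
    scores = pca_scores(table)
    tables["pca_scores"] = scores.scores.round(6)
    report["pca_explained"] = [round(float(e), 4) for e in scores.explained]

    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "stage_seeds": stage_seeds,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "tables": sorted(tables),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=name in ("de", "pca_scores"))
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest, report
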