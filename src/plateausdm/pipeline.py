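"""End-to-end pipeline: synthetic inputs -> thinning -> screening -> models
-> binary maps -> consensus -> overlay -> tables.

Stages communicate only through files under the output directory, so each
command-line verb can re-run a stage in isolation, and a full run is
reproducible byte-for-byte from the configuration and master seed. The
master seed fans out to per-stage / per-species / per-replicate seeds
through a hash-based derivation scheme (see :func:`plateausdm._util.derive_seed`).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import __version__
from ._util import derive_seed, log_stage
from .binary import BinaryMap, binarize, consensus_intersection
from .config import RunConfig
from .maxent import project_mean_logistic, run_replicates
from .occurrences import SPECIES, read_occurrences, write_occurrences
from .overlay import (centroid, centroid_shift, classify_scenarios,
                      percent_change, prey_layer, zonal_areas)
from .raster import RasterStack, align_stack, read_raster, write_raster
from .screening import pairwise_correlation, screen_stack
from .synthetic import (ScenarioSpec, TrueModel, generate_env_stack,
                        generate_regions, perturb_future, sample_occurrences,
                        true_suitability)
from .thinning import thin_occurrences

RCP_SCENARIOS = ("RCP2.6", "RCP4.5", "RCP8.5")


@dataclass
class SynthDesign:
    """Desk-scale synthetic study design.

    The landscape is a 150 x 150 grid of nominal 1-km cells carrying all
    eight environmental variables. Raw occurrence counts mirror the field
    survey (585 bears, 308 marmots, 311 pikas before thinning); each
    emissions scenario is emulated by three noise-perturbed variant stacks
    standing in for distinct climate models, with progressively stronger
    climate shifts and land-cover degradation from RCP2.6 to RCP8.5.
    """

    shape: tuple = (150, 150)
    autocorr_range: float = 6.0
    n_lucc_classes: int = 4
    k_regions: int = 6
    raw_counts: Dict[str, int] = field(default_factory=lambda: {
        "bear": 585, "marmot": 308, "pika": 311})
    n_gcm_variants: int = 3

    def true_models(self) -> Dict[str, TrueModel]:
        deg = self.n_lucc_classes  # highest code doubles as the degraded class
        return {
            "bear": TrueModel(
                linear_coeffs={"Bio3": 1.5, "Bio12": 1.0, "ELE": 1.0},
                quadratic_coeffs={"ELE": -0.5},
                class_offsets={"LUCC": {1: 0.5, deg: -1.0}},
                prevalence_target=0.25),
            "marmot": TrueModel(
                linear_coeffs={"Bio12": 1.2, "Bio2": -0.8, "HII": -1.0},
                class_offsets={"LUCC": {1: 1.0, deg: -1.5}},
                prevalence_target=0.30),
            "pika": TrueModel(
                linear_coeffs={"Bio12": 1.5, "Bio15": -0.8},
                class_offsets={"LUCC": {1: 1.5, deg: -2.0}},
                prevalence_target=0.30),
        }

    def scenario_specs(self) -> List[ScenarioSpec]:
        n, deg = self.n_gcm_variants, self.n_lucc_classes
        return [
            ScenarioSpec("RCP2.6", shifts={"Bio12": -0.1, "Bio2": 0.1},
                         lucc_transition_fraction=0.02, n_gcm_variants=n,
                         variant_noise_sd=0.05, degraded_class=deg),
            ScenarioSpec("RCP4.5", shifts={"Bio12": -0.3, "Bio2": 0.2, "Bio15": 0.15},
                         lucc_transition_fraction=0.05, n_gcm_variants=n,
                         variant_noise_sd=0.08, degraded_class=deg),
            ScenarioSpec("RCP8.5", shifts={"Bio12": -0.6, "Bio2": 0.4,
                                           "Bio15": 0.3, "Bio17": -0.3},
                         lucc_transition_fraction=0.12, n_gcm_variants=n,
                         variant_noise_sd=0.12, degraded_class=deg),
        ]


# -- stage: inputs --------------------------------------------------------


def stage_synth_inputs(outdir: Path, config: RunConfig,
                       design: SynthDesign | None = None) -> None:
    """Generate and write all synthetic inputs (stacks, occurrences, regions)."""
    design = design or SynthDesign()
    seed = config.random_seed
    inputs = Path(outdir) / "inputs"
    from .raster import VARIABLE_VOCAB
    stack = generate_env_stack(design.shape, list(VARIABLE_VOCAB),
                               design.autocorr_range,
                               seed=derive_seed(seed, "stack"),
                               n_lucc_classes=design.n_lucc_classes,
                               cell_size=config.cell_size_km)
    for name, layer in stack.layers.items():
        p = inputs / "current" / f"{name}.tif"
        p.parent.mkdir(parents=True, exist_ok=True)
        write_raster(layer, p)
    regions = generate_regions(design.shape, design.k_regions,
                               seed=derive_seed(seed, "regions"),
                               cell_size=config.cell_size_km)
    write_raster(regions, inputs / "regions.tif")
    truths = design.true_models()
    for sp in SPECIES:
        truth = true_suitability(stack, truths[sp])
        occ = sample_occurrences(truth, design.raw_counts[sp],
                                 seed=derive_seed(seed, "occ", sp), species=sp)
        write_occurrences(occ, inputs / f"occurrences_{sp}.csv")
    for spec in design.scenario_specs():
        variants = perturb_future(stack, spec,
                                  seed=derive_seed(seed, "future", spec.scenario_tag))
        for i, vstack in enumerate(variants):
            for name, layer in vstack.layers.items():
                p = inputs / "future" / spec.scenario_tag / f"gcm{i + 1}" / f"{name}.tif"
                p.parent.mkdir(parents=True, exist_ok=True)
                write_raster(layer, p)
    log_stage("synth_inputs", outdir=str(outdir), seed=seed)


def _read_stack_dir(path: Path, tag: str) -> RasterStack:
    layers = {}
    for tif in sorted(path.glob("*.tif")):
        layers[tif.stem] = read_raster(tif)
    if not layers:
        raise FileNotFoundError(f"no raster layers found under {path}")
    return align_stack(layers, scenario_tag=tag)


def load_inputs(outdir: Path):
    """Load current stack, future variant stacks, regions and occurrences."""
    inputs = Path(outdir) / "inputs"
    if not inputs.exists():
        raise FileNotFoundError(f"missing inputs directory: {inputs}")
    stack = _read_stack_dir(inputs / "current", "current")
    regions = read_raster(inputs / "regions.tif")
    occ = {sp: read_occurrences(inputs / f"occurrences_{sp}.csv", species=sp)
           for sp in SPECIES}
    futures: Dict[str, List[RasterStack]] = {}
    fdir = inputs / "future"
    if fdir.exists():
        for scen_dir in sorted(fdir.iterdir()):
            variants = []
            for gcm_dir in sorted(scen_dir.iterdir()):
                variants.append(_read_stack_dir(gcm_dir, f"{scen_dir.name}/{gcm_dir.name}"))
            futures[scen_dir.name] = variants
    return stack, futures, regions, occ


# -- stage: fit -----------------------------------------------------------


def stage_fit(outdir: Path, config: RunConfig) -> None:
    """Thin occurrences, screen variables, fit replicate models, and write
    mean suitability maps (current + every future variant) and thresholds."""
    outdir = Path(outdir)
    stack, futures, _, occ = load_inputs(outdir)
    seed = config.random_seed

    screening = screen_stack(stack, cutoff=config.correlation_cutoff)
    cm = pairwise_correlation(stack)
    cm.to_frame().to_csv(outdir / "correlation_matrix.csv", float_format="%.6f")
    with open(outdir / "screening.json", "w") as fh:
        json.dump({"kept": screening.all_kept(),
                   "dropped": [{"name": n, "max_abs_r": None if r != r else round(r, 6),
                                "partner": p} for n, r, p in screening.dropped]},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    kept = screening.all_kept()
    stack = stack.subset(kept)
    futures = {s: [v.subset(kept) for v in vs] for s, vs in futures.items()}

    thin_cell = config.thinning_cell_km  # map units are km on the synthetic grid
    thresholds: Dict[str, float] = {}
    for sp, occ_sp in occ.items():
        thinned, report = thin_occurrences(occ_sp, stack.grid, thin_cell,
                                           seed=derive_seed(seed, "thin", sp))
        spdir = outdir / sp
        spdir.mkdir(parents=True, exist_ok=True)
        write_occurrences(thinned, spdir / "thinned.csv")
        with open(spdir / "thinning.json", "w") as fh:
            json.dump(asdict(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        result = run_replicates(stack, thinned, config,
                                master_seed=derive_seed(seed, "replicates", sp))
        cur = spdir / "current"
        cur.mkdir(parents=True, exist_ok=True)
        write_raster(result.mean_logistic, cur / "suitability.tif")
        result.report.per_replicate.to_csv(cur / "eval.csv", index=False,
                                           float_format="%.6f")
        with open(cur / "eval.json", "w") as fh:
            json.dump({**result.report.aggregates(),
                       "percent_contribution": {k: round(v, 4) for k, v in
                                                result.report.percent_contribution.items()}},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
        thresholds[sp] = result.threshold
        for scen, variants in futures.items():
            for i, vstack in enumerate(variants):
                proj = project_mean_logistic(result.models, vstack)
                p = spdir / scen / f"gcm{i + 1}" / "suitability.tif"
                p.parent.mkdir(parents=True, exist_ok=True)
                write_raster(proj, p)
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump({k: round(v, 6) for k, v in thresholds.items()}, fh,
                  indent=2, sort_keys=True)
        fh.write("\n")


# -- stage: binarize ------------------------------------------------------


def stage_binarize(outdir: Path, config: RunConfig) -> None:
    """Threshold suitability maps with the replicate-mean MTSPS and take the
    consensus intersection across variant maps for each future scenario."""
    outdir = Path(outdir)
    with open(outdir / "thresholds.json") as fh:
        thresholds = json.load(fh)
    for sp in SPECIES:
        t = thresholds[sp]
        spdir = outdir / sp
        suit = read_raster(spdir / "current" / "suitability.tif")
        bm = binarize(suit, t, species=sp, scenario_tag="current")
        write_raster(bm.raster, spdir / "current" / "binary.tif")
        for scen_dir in sorted(p for p in spdir.iterdir()
                               if p.is_dir() and p.name.startswith("RCP")):
            variant_maps = []
            for gcm_dir in sorted(scen_dir.glob("gcm*")):
                suit = read_raster(gcm_dir / "suitability.tif")
                variant_maps.append(binarize(suit, t, species=sp,
                                             scenario_tag=f"{scen_dir.name}/{gcm_dir.name}"))
            consensus = consensus_intersection(variant_maps)
            write_raster(consensus.raster, scen_dir / "binary.tif")


# -- stage: overlay -------------------------------------------------------


def _load_binary(outdir: Path, sp: str, scen: str, threshold: float) -> BinaryMap:
    r = read_raster(Path(outdir) / sp / scen / "binary.tif")
    vals = r.values.astype(bool)
    return BinaryMap(raster=r.copy_with(values=vals), threshold_used=threshold,
                     species=sp, scenario_tag=scen)


def stage_overlay(outdir: Path, config: RunConfig, prey_rule: str = "union") -> None:
    """Classify S1/S2/S3, compute zonal areas, changes and centroid shifts."""
    outdir = Path(outdir)
    regions = read_raster(Path(outdir) / "inputs" / "regions.tif")
    with open(outdir / "thresholds.json") as fh:
        thresholds = json.load(fh)
    cell_area = config.cell_size_km ** 2
    scenarios = ["current"] + [s for s in RCP_SCENARIOS
                               if (outdir / "bear" / s).exists()]
    odir = outdir / "overlay"
    odir.mkdir(parents=True, exist_ok=True)

    table2_rows, table3_rows, change_rows, centroid_rows = [], [], [], []
    areas_by = {}   # (kind, label, scen) -> total km2
    cent_by = {}
    for scen in scenarios:
        maps = {sp: _load_binary(outdir, sp, scen, thresholds[sp]) for sp in SPECIES}
        prey = prey_layer(maps["marmot"], maps["pika"], rule=prey_rule)
        part = classify_scenarios(maps["bear"], prey, prey_rule=prey_rule)
        pdir = odir / scen
        pdir.mkdir(parents=True, exist_ok=True)
        write_raster(part.classes, pdir / "partition.tif")
        for sp in SPECIES:
            za = zonal_areas(maps[sp], regions, cell_area)
            table2_rows.append(za)
            areas_by[("species", sp, scen)] = float(za["area_km2"].sum())
            if maps[sp].suitable_count > 0:
                c = centroid(maps[sp])
                cent_by[(sp, scen)] = c
                centroid_rows.append({"species": sp, "scenario_tag": scen,
                                      "x": c.x, "y": c.y})
            else:
                log_stage("overlay", species=sp, scenario=scen,
                          warning="empty habitat; centroid skipped")
        zs = zonal_areas(part, regions, cell_area)
        table3_rows.append(zs)
        counts = part.counts()
        n_valid = int(part.classes.valid_mask.sum())
        for cls in ("S1", "S2", "S3"):
            areas_by[("class", cls, scen)] = counts[cls] * cell_area
            table3_rows.append(pd.DataFrame([{
                "label": f"{cls}_total", "region": "ALL", "scenario_tag": scen,
                "area_km2": counts[cls] * cell_area,
                "proportion_pct": 100.0 * counts[cls] / n_valid}]))

    for scen in scenarios[1:]:
        for kind, label in ([("species", sp) for sp in SPECIES]
                            + [("class", c) for c in ("S1", "S2", "S3")]):
            base = areas_by.get((kind, label, "current"), 0.0)
            fut = areas_by.get((kind, label, scen), 0.0)
            pc = percent_change(base, fut) if base > 0 else float("nan")
            change_rows.append({"kind": kind, "label": label, "scenario_tag": scen,
                                "baseline_km2": base, "future_km2": fut,
                                "percent_change": pc})
        for sp in SPECIES:
            if (sp, "current") in cent_by and (sp, scen) in cent_by:
                dist, bearing = centroid_shift(cent_by[(sp, "current")], cent_by[(sp, scen)])
                centroid_rows.append({"species": sp, "scenario_tag": f"current->{scen}",
                                      "x": round(dist, 6), "y": round(bearing, 6)})

    pd.concat(table2_rows, ignore_index=True).to_csv(
        odir / "table2_zonal_areas.csv", index=False, float_format="%.6f")
    pd.concat(table3_rows, ignore_index=True).to_csv(
        odir / "table3_scenario_classes.csv", index=False, float_format="%.6f")
    pd.DataFrame(change_rows).to_csv(odir / "changes.csv", index=False,
                                     float_format="%.6f")
    pd.DataFrame(centroid_rows).to_csv(odir / "centroids.csv", index=False,
                                       float_format="%.6f")

    summary = {
        "scenarios": scenarios,
        "thresholds": {k: round(v, 6) for k, v in thresholds.items()},
        "areas_km2": {f"{kind}:{label}:{scen}": round(v, 4)
                      for (kind, label, scen), v in sorted(areas_by.items())},
        "percent_changes": {f"{r['kind']}:{r['label']}:{r['scenario_tag']}":
                            (None if r["percent_change"] != r["percent_change"]
                             else r["percent_change"]) for r in change_rows},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# -- manifest and report --------------------------------------------------


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, config: RunConfig, mode: str) -> dict:
    outdir = Path(outdir)
    inputs = sorted((outdir / "inputs").rglob("*")) if (outdir / "inputs").exists() else []
    manifest = {
        "version": __version__,
        "mode": mode,
        "config": asdict(config),
        "seed": config.random_seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "input_hashes": {str(p.relative_to(outdir)): _hash_file(p)
                         for p in inputs if p.is_file()},
        "outputs": sorted(str(p.relative_to(outdir))
                          for p in outdir.rglob("*")
                          if p.is_file() and p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_pipeline(config: RunConfig, outdir: str | os.PathLike,
                 mode: str = "synthetic", design: SynthDesign | None = None,
                 prey_rule: str = "union") -> dict:
    """Execute every stage in order and return the run manifest.

    In synthetic mode all inputs are generated under ``outdir/inputs``; in
    user-data mode they must already be laid out there in the same structure
    (current/ stack, future/<scenario>/<variant>/ stacks, regions.tif,
    occurrences_<species>.csv).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    if mode == "synthetic":
        stage_synth_inputs(outdir, config, design)
    elif mode != "user-data":
        raise ValueError(f"unknown mode {mode!r}")
    stage_fit(outdir, config)
    stage_binarize(outdir, config)
    stage_overlay(outdir, config, prey_rule=prey_rule)
    manifest = write_manifest(outdir, config, mode)
    make_report(outdir)
    return manifest


def make_report(outdir: str | os.PathLike) -> str:
    """Render a human-readable summary (AUCs, thresholds, contributions,
    areas, changes, centroid shifts) and write it to ``report.txt``."""
    outdir = Path(outdir)
    with open(outdir / "summary.json") as fh:
        summary = json.load(fh)
    lines = ["Habitat pipeline summary", "=" * 24, ""]
    lines.append("MTSPS thresholds (replicate means):")
    for sp, t in summary["thresholds"].items():
        lines.append(f"  {sp}: {t:.4f}")
    lines.append("")
    for sp in SPECIES:
        eval_path = outdir / sp / "current" / "eval.json"
        if eval_path.exists():
            with open(eval_path) as fh:
                ev = json.load(fh)
            lines.append(f"{sp}: train AUC {ev['train_auc_mean']:.3f} "
                         f"(sd {ev['train_auc_sd']:.3f}), "
                         f"test AUC {ev['test_auc_mean']:.3f} "
                         f"(sd {ev['test_auc_sd']:.3f})")
            top = sorted(ev["percent_contribution"].items(),
                         key=lambda kv: -kv[1])[:3]
            lines.append("  top contributions: "
                         + ", ".join(f"{k} {v:.1f}%" for k, v in top))
    lines.append("")
    lines.append("Range and class areas (km^2):")
    for key, v in summary["areas_km2"].items():
        lines.append(f"  {key}: {v:.2f}")
    lines.append("")
    lines.append("Percent changes vs current:")
    for key, v in summary["percent_changes"].items():
        lines.append(f"  {key}: {'n/a' if v is None else f'{v:+.2f}%'}")
    cent = outdir / "overlay" / "centroids.csv"
    if cent.exists():
        df = pd.read_csv(cent)
        shifts = df[df["scenario_tag"].astype(str).str.contains("->")]
        if not shifts.empty:
            lines.append("")
            lines.append("Centroid shifts (distance km, bearing deg cw from N):")
            for _, r in shifts.iterrows():
                lines.append(f"  {r['species']} {r['scenario_tag']}: "
                             f"{r['x']:.2f} km at {r['y']:.1f} deg")
    text = "\n".join(lines) + "\n"
    with open(outdir / "report.txt", "w") as fh:
        fh.write(text)
    return text
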