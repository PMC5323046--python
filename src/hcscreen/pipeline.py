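"""End-to-end orchestration of the screen and fixture generation.

``run_screen`` drives the synthetic primary screen through normalization,
quality reporting, hit calling, ranking and deconvolution validation, and
persists every stage as CSV/JSON when an output directory is given.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hitcalling, platestats, synthgen
from .errors import HcscreenError

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "n_genes": 20,
    "markers": list(synthgen.MARKERS),
    "effects": {},            # gene -> [spot fold, iss fold]
    "toxic_sirnas": {},       # sirna -> {cell_count_fold, morphology_fold}
    "knockdown": {},          # sirna -> residual fraction
    "baseline": {},           # overrides for synthgen.Baseline fields
    "thresholds": {},         # marker -> SD multiplier overrides
    "top_n": 10,
    "sd_mode": "pooled",
    "treatments": ["none"],
}

KNOWN_KEYS = set(DEFAULT_CONFIG)


def resolve_config(config: dict | None) -> dict:
    config = dict(config or {})
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise HcscreenError(f"unknown config keys: {sorted(unknown)}")
    resolved = dict(DEFAULT_CONFIG)
    resolved.update(config)
    return resolved


def build_model(config: dict) -> synthgen.EffectModel:
    baseline = synthgen.Baseline(**config.get("baseline", {}))
    toxic = {s: synthgen.ToxicEffect(**spec_) if isinstance(spec_, dict)
             else spec_ for s, spec_ in config.get("toxic_sirnas", {}).items()}
    effects = {g: tuple(v) for g, v in config.get("effects", {}).items()}
    return synthgen.EffectModel(
        gene_effects=effects, toxic_sirnas=toxic,
        knockdown=dict(config.get("knockdown", {})),
        baseline=baseline, seed=int(config["seed"]))


def quality_report(wells: pd.DataFrame) -> dict:
    """z'-factor per marker and parameter from positive/negative controls."""
    report = {"markers": {}}
    for marker, grp in wells.groupby("marker"):
        pos = grp[grp["control_class"] == "positive"]
        neg = grp[grp["control_class"] == "negative"]
        entry = {}
        for p in platestats.PARAMETERS:
            entry[p] = platestats.zprime(pos[p].dropna(), neg[p].dropna())
        report["markers"][marker] = entry
    report["min_zprime"] = float(min(
        v for e in report["markers"].values() for v in e.values()))
    return report


def run_screen(config: dict | None = None, outdir=None) -> dict:
    """Run the full synthetic screen: simulate -> normalize -> call ->
    rank -> deconvolute.

    Returns a results bundle of DataFrames plus the quality report and the
    resolved configuration; writes each stage to ``outdir`` when given.
    """
    config = resolve_config(config)
    seed = int(config["seed"])
    model = build_model(config)
    thresholds = hitcalling.HitThresholds()
    thresholds.k.update({m: float(k)
                         for m, k in config.get("thresholds", {}).items()})

    log.info("stage=simulate seed=%d n_genes=%s markers=%d",
             seed, config["n_genes"], len(config["markers"]))
    layout = synthgen.make_screen_layout(
        config["n_genes"], markers=config["markers"], sirnas_per_gene=1,
        seed=seed, treatments=tuple(config["treatments"]))
    wells = synthgen.simulate_well_table(layout, model)

    quality = quality_report(wells)
    normalized = platestats.normalize_to_control(wells, sd_mode=config["sd_mode"])
    verdicts = hitcalling.call_primary_hits(normalized, thresholds)
    candidates = hitcalling.rank_candidates(verdicts, top_n=int(config["top_n"]))
    candidate_genes = sorted(set(candidates["gene"])) if len(candidates) else []
    log.info("stage=primary hits=%d candidates=%d",
             int(verdicts["is_hit"].sum()), len(candidate_genes))

    results = {
        "config": config, "layout": layout.wells, "wells": wells,
        "quality": quality, "normalized": normalized, "verdicts": verdicts,
        "candidates": candidates,
    }

    if candidate_genes:
        deconv_layout = synthgen.make_screen_layout(
            candidate_genes, markers=config["markers"], sirnas_per_gene=4,
            seed=seed + 1, treatments=tuple(config["treatments"]))
        deconv_wells = synthgen.simulate_well_table(deconv_layout, model)
        deconv_norm = platestats.normalize_to_control(
            deconv_wells, sd_mode=config["sd_mode"])
        deconv_verdicts = hitcalling.call_primary_hits(deconv_norm, thresholds)
        toxicity = hitcalling.flag_toxicity(deconv_wells)
        validated = hitcalling.deconvolute(deconv_verdicts, toxicity)
        results.update({
            "deconv_wells": deconv_wells, "deconv_normalized": deconv_norm,
            "deconv_verdicts": deconv_verdicts, "toxicity": toxicity,
            "validated": validated,
        })
        log.info("stage=deconvolution validated=%d",
                 int((validated["stage"] == "validated").sum()))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        with open(outdir / "quality_report.json", "w") as fh:
            json.dump(quality, fh, indent=2)
        for name in ("layout", "wells", "normalized", "verdicts", "candidates",
                     "deconv_wells", "deconv_normalized", "deconv_verdicts",
                     "toxicity", "validated"):
            if name in results:
                results[name].to_csv(outdir / f"{name}.csv", index=False)
    return results


def validated_genes(results: dict) -> dict:
    """Genes validated for >= 1 marker, with the per-marker split."""
    if "validated" not in results:
        return {"genes": [], "per_marker": {}}
    v = results["validated"]
    ok = v[v["stage"] == "validated"]
    per_marker = {m: sorted(set(g["gene"]))
                  for m, g in ok.groupby("marker")}
    return {"genes": sorted(set(ok["gene"])), "per_marker": per_marker}


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_PROFILES = ("small-screen", "imaging-demo", "apms-demo", "qpcr-demo",
                    "expression-demo")


def make_fixtures(profile: str, seed: int = 0, outdir=".") -> list:
    """Write self-contained input files plus ground-truth sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save_csv(df, name):
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    if profile == "small-screen":
        effects = {f"GENE{i:03d}": [2.5, 2.5] for i in (3, 7, 11)}
        config = {"seed": seed, "n_genes": 20, "effects": effects}
        model = build_model(resolve_config(config))
        layout = synthgen.make_screen_layout(20, seed=seed)
        wells = synthgen.simulate_well_table(layout, model)
        save_csv(layout.wells, "plate_map.csv")
        save_csv(wells, "well_table.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"effects": effects, "seed": seed}, fh, indent=2)
        written.append(outdir / "truth.json")
    elif profile == "imaging-demo":
        import tifffile
        truths = {}
        for i in range(4):
            img, truth = synthgen.render_well_image(
                n_cells=8, spots_per_cell=5, size=256, seed=seed + i)
            path = outdir / f"well_{i:02d}.tiff"
            tifffile.imwrite(path, img)
            truths[path.name] = truth
            written.append(path)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truths, fh, indent=2)
        written.append(outdir / "truth.json")
    elif profile == "apms-demo":
        network = {"BAITA": {"PREY01": 20, "PREY02": 12},
                   "BAITB": {"PREY03": 15}}
        freq = {f"BG{i:02d}": 0.4 for i in range(20)}
        runs = synthgen.simulate_apms(30, network, freq, seed=seed)
        save_csv(runs, "spectral_counts.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"network": network, "seed": seed}, fh, indent=2)
        written.append(outdir / "truth.json")
    elif profile == "qpcr-demo":
        kd = {"GENEA": 0.25, "GENEB": 0.6}
        ct = synthgen.simulate_qpcr(list(kd), kd, seed=seed)
        save_csv(ct.data, "ct_table.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"knockdown": kd, "seed": seed}, fh, indent=2)
        written.append(outdir / "truth.json")
    elif profile == "expression-demo":
        truth = {"GENE001": 1.8, "GENE002": 0.5, "GENE003": 1.0}
        tables = synthgen.simulate_expression(50, truth, noise_sd=0.05,
                                              seed=seed)
        for i, t in enumerate(tables, start=1):
            save_csv(t, f"ratios_exp{i}.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"de_truth": truth, "seed": seed}, fh, indent=2)
        written.append(outdir / "truth.json")
    else:
        raise HcscreenError(
            f"unknown fixture profile {profile!r}; known: {FIXTURE_PROFILES}")
    return written


# ---------------------------------------------------------------------------
# Canonical end-to-end benchmark
# ---------------------------------------------------------------------------

def end_to_end_benchmark(n_genes: int = 186, n_true_hits: int = 10,
                         fold: float = 2.5, seed: int = 42) -> dict:
    """Synthetic screen with planted hits; reports recovery statistics."""
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    true_hits = sorted(rng.choice(genes, size=n_true_hits, replace=False))
    config = {"seed": seed, "n_genes": n_genes,
              "effects": {g: [fold, fold] for g in true_hits}}
    results = run_screen(config)
    primary = set(results["verdicts"].loc[results["verdicts"]["is_hit"],
                                          "gene"])
    val = validated_genes(results)
    validated = set(val["genes"])
    return {
        "true_hits": true_hits,
        "primary_hits": sorted(primary),
        "true_primary": sorted(set(true_hits) & primary),
        "validated": sorted(validated),
        "true_validated": sorted(set(true_hits) & validated),
        "false_validated": sorted(validated - set(true_hits)),
        "quality": results["quality"],
        "results": results,
    }
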