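"""Pipeline runner: simulate/load -> normalize -> QC -> hits (+ validation stages).

A run is described by a configuration dict (usually from YAML) with a
``stages`` list and one block per stage. Every run writes per-stage CSVs
plus a single ``report.json`` embedding the fully resolved configuration and
seed, so a run can be reproduced from its own report. The timestamp is
isolated in one field; all other output is a deterministic function of
(config, seed).
"""

from __future__ import annotations

import datetime
import json
import logging
import pathlib

import pandas as pd

from . import plate, screen, simulate, validate, imaging
from .errors import ConfigError, PipelineError, HTSError

log = logging.getLogger(__name__)

KNOWN_STAGES = ("screen", "qpcr", "microct", "stain", "nuclei")
_TOP_KEYS = {"stages", "log_level"} | set(KNOWN_STAGES)


def _resolve_config(config: dict) -> dict:
    if not isinstance(config, dict):
        raise ConfigError("run config must be a mapping")
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown run-config key(s): {sorted(unknown)}")
    stages = config.get("stages")
    if not stages:
        raise ConfigError("run config must select at least one stage")
    bad = set(stages) - set(KNOWN_STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")
    for stage in stages:
        if stage not in config:
            raise ConfigError(f"stage '{stage}' selected but has no config block")
    return config


def _screen_sim_config(block: dict) -> simulate.ScreenSimConfig:
    block = dict(block or {})
    if block.pop("paperlike", False):
        keys = {"n_activators", "n_inhibitors", "activator_multiplier",
                "inhibitor_multiplier"}
        kw = {k: block.pop(k) for k in list(block) if k in keys}
        base = simulate.paperlike_config(**kw, **block)
        return base
    return simulate.ScreenSimConfig.from_dict(block)


def _run_screen(block: dict, seed: int, outdir: pathlib.Path) -> dict:
    hc = screen.HitCallingConfig.from_dict(block.get("hit_calling", {}) or {})
    if "simulate" in block:
        cfg = _screen_sim_config(block["simulate"])
        dataset, truth = simulate.simulate_screen(cfg, seed=seed)
        plate.write_measurements(dataset, outdir / "measurements.csv")
        plate.write_results(outdir / "truth_compounds.csv", truth.compounds)
        plate.write_results(outdir / "truth_plates.csv", truth.plates)
        resolved_sim = cfg.to_dict()
    elif "measurements" in block and "layouts" in block:
        layout_dir = pathlib.Path(block["layouts"])
        layouts = {p.stem: plate.read_layout(p) for p in sorted(layout_dir.glob("*.csv"))}
        if not layouts:
            raise ConfigError(f"no layout CSVs in {layout_dir}")
        dataset = plate.read_measurements(block["measurements"], layouts)
        resolved_sim = None
    else:
        raise ConfigError("screen stage needs either a 'simulate' block or "
                          "'measurements' + 'layouts' paths")

    metrics = screen.compute_well_metrics(dataset)
    qc = screen.qc_screen(metrics, qc_threshold=hc.qc_threshold)
    hits = screen.call_hits(dataset, hc, metrics=metrics, qc=qc)

    out_cols = [c for c in metrics.columns if c != "valid"] + ["valid"]
    plate.write_results(outdir / "well_metrics.csv", metrics.loc[:, out_cols])
    plate.write_results(outdir / "plate_qc.csv", qc)
    plate.write_results(outdir / "hits.csv", hits.calls)
    plate.write_results(outdir / "hit_observations.csv", hits.observations)

    counts = hits.counts()
    return {
        "config": {"simulate": resolved_sim,
                   "hit_calling": screen.hit_config_to_dict(hc)},
        "wells_loaded": dataset.load_report["loaded"],
        "wells_valid": dataset.load_report["valid"],
        "wells_invalid": dataset.load_report["invalid"],
        "plates_total": int(len(qc)),
        "plates_pass_qc": int(qc["pass"].sum()),
        "hits_activator": counts["activator"],
        "hits_inhibitor": counts["inhibitor"],
        "hits_total": counts["activator"] + counts["inhibitor"],
        "outputs": ["well_metrics.csv", "plate_qc.csv", "hits.csv",
                    "hit_observations.csv"],
    }


def _run_qpcr(block: dict, seed: int, outdir: pathlib.Path) -> dict:
    block = dict(block or {})
    target = block.get("target", "ACVR1")
    references = block.get("references", ["GAPDH", "B2M"])
    if "simulate" in block:
        sim = dict(block["simulate"])
        folds = sim.pop("true_folds")
        table, _truth = simulate.simulate_ct_table(
            folds, references=references, target=target, seed=seed, **sim)
        plate.write_results(outdir / "ct_table.csv", table)
    elif "ct_table" in block:
        table = pd.read_csv(block["ct_table"])
    else:
        raise ConfigError("qpcr stage needs a 'simulate' block or a 'ct_table' path")
    calibrator = block.get("calibrator")
    if calibrator:
        rel = validate.normalized_fold_expression(table, target, references, calibrator)
    else:
        rel = validate.relative_expression(table, target, references)
    plate.write_results(outdir / "expression.csv", rel)
    return {"config": {k: v for k, v in block.items() if k != "ct_table"} |
            {"target": target, "references": list(references)},
            "samples": int(rel["sample_id"].nunique()),
            "outputs": ["expression.csv"]}


def _run_microct(block: dict, seed: int, outdir: pathlib.Path) -> dict:
    block = dict(block or {})
    if "hu_threshold" not in block:
        raise ConfigError("microct stage requires an explicit 'hu_threshold'")
    thr = float(block["hu_threshold"])
    if "simulate" in block:
        vol, truth = simulate.simulate_hu_volume(seed=seed, **(block["simulate"] or {}))
    elif "volume" in block:
        vol, truth = imaging.load_volume(block["volume"]), None
    else:
        raise ConfigError("microct stage needs a 'simulate' block or a 'volume' path")
    seg = imaging.segment_mineralized(vol, thr, int(block.get("min_component", 0)))
    row = {"hu_threshold": thr, "n_voxels": seg.n_voxels,
           "volume_mm3": seg.volume_mm3, "density_hu_per_mm3": seg.density_hu_per_mm3,
           "density_defined": seg.density_defined}
    if truth:
        row["analytic_volume_mm3"] = truth["analytic_volume_mm3"]
    plate.write_results(outdir / "microct.csv", pd.DataFrame([row]))
    return {"config": block, "volume_mm3": seg.volume_mm3, "outputs": ["microct.csv"]}


def _run_stain(block: dict, seed: int, outdir: pathlib.Path) -> dict:
    block = dict(block or {})
    if "simulate" in block:
        img, _truth = simulate.simulate_stain_image(seed=seed, **(block["simulate"] or {}))
    elif "image" in block:
        import imageio.v3 as iio
        img = iio.imread(block["image"])
    else:
        raise ConfigError("stain stage needs a 'simulate' block or an 'image' path")
    res = imaging.stain_positive_area(img)
    plate.write_results(outdir / "stain.csv", pd.DataFrame([{
        "positive_pixels": res.positive_pixels,
        "total_tissue_pixels": res.total_tissue_pixels,
        "fraction": res.fraction}]))
    return {"config": block, "fraction": res.fraction, "outputs": ["stain.csv"]}


def _run_nuclei(block: dict, seed: int, outdir: pathlib.Path) -> dict:
    block = dict(block or {})
    thr = float(block.get("intensity_threshold", 100))
    min_size = int(block.get("min_size", 1))
    if "simulate" in block:
        img, _truth = simulate.simulate_nuclei_image(seed=seed, **(block["simulate"] or {}))
    elif "image" in block:
        import imageio.v3 as iio
        img = iio.imread(block["image"])
    else:
        raise ConfigError("nuclei stage needs a 'simulate' block or an 'image' path")
    res = imaging.count_nuclei(img, thr, min_size)
    plate.write_results(outdir / "nuclei.csv", pd.DataFrame([{
        "count": res.count, "intensity_threshold": thr, "min_size": min_size}]))
    return {"config": block, "count": res.count, "outputs": ["nuclei.csv"]}


_RUNNERS = {"screen": _run_screen, "qpcr": _run_qpcr, "microct": _run_microct,
            "stain": _run_stain, "nuclei": _run_nuclei}


def run_pipeline(config: dict, seed: int, outdir) -> dict:
    """Execute the selected stages; write per-stage CSVs and report.json.

    Any stage failure leaves a ``FAILED`` marker naming the stage and
    re-raises as :class:`PipelineError`. Returns the report dict.
    """
    config = _resolve_config(config)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": int(seed), "stages": {},
              "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat()}
    for stage in config["stages"]:
        log.info("running stage %s", stage)
        try:
            report["stages"][stage] = _RUNNERS[stage](config.get(stage) or {},
                                                      seed, outdir)
        except HTSError:
            (outdir / "FAILED").write_text(f"stage: {stage}\n")
            raise
        except Exception as exc:  # noqa: BLE001 - annotate the stage and re-raise
            (outdir / "FAILED").write_text(f"stage: {stage}\n")
            raise PipelineError(stage, str(exc)) from exc
    report["config"] = config
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                   default=str) + "\n")
    return report
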