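"""End-to-end orchestration: simulate/load -> call -> annotate -> summarize
-> compare, with a machine-readable run report.

A run is described by a config mapping (usually parsed from YAML) with
per-condition inputs (either a simulation block or paths to real SAM/
FASTA/annotation/VCF files), a shared filter block, a baseline condition,
and a seed. Reruns with the same config and seed reproduce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as eio
from .annotate import GenomeAnnotation, annotate_calls
from .calling import (call_rdd_sites, write_calls_tsv, write_calls_vcf,
                      FILTER_NAMES)
from .config import (ConfigError, FilterConfig, SimConfig,
                     filter_config_from_dict, sim_config_from_dict)
from .pileup import build_pileup
from .simulate import simulate_dataset
from .summarize import compare_editomes, summarize_editome

log = logging.getLogger("editome")

_REAL_KEYS = ("sam", "reference", "annotation")


@dataclass
class ConditionSpec:
    label: str
    sim: SimConfig | None = None
    paths: dict | None = None  # sam, reference, annotation, snp_mask


@dataclass
class PipelineConfig:
    conditions: list[ConditionSpec]
    baseline: str
    filters: FilterConfig = field(default_factory=FilterConfig)
    outdir: str = "editome_run"
    seed: int = 0
    log_level: str = "INFO"


def validate_config(raw: dict) -> PipelineConfig:
    """Normalize a raw config mapping, filling defaults.

    Raises ConfigError listing every problem found (missing/duplicate
    condition labels, neither-or-both input blocks, missing paths, filter
    threshold violations, absent baseline).
    """
    errors: list[str] = []
    raw = dict(raw or {})
    try:
        filters = filter_config_from_dict(raw.get("filters"))
    except ConfigError as exc:
        errors.append(f"filters: {exc}")
        filters = FilterConfig()
    seed = int(raw.get("seed", 0))

    conditions: list[ConditionSpec] = []
    labels: list[str] = []
    for i, block in enumerate(raw.get("conditions", [])):
        label = str(block.get("label", "")) or f"condition{i + 1}"
        if label in labels:
            errors.append(f"duplicate condition label {label!r}")
        labels.append(label)
        has_sim = "sim" in block
        has_real = any(k in block for k in _REAL_KEYS)
        if has_sim == has_real:
            errors.append(f"condition {label!r}: provide exactly one of a "
                          f"'sim' block or real input paths {_REAL_KEYS}")
            continue
        if has_sim:
            sim_raw = dict(block["sim"] or {})
            sim_raw.setdefault("seed", seed + i)
            try:
                conditions.append(
                    ConditionSpec(label, sim=sim_config_from_dict(sim_raw)))
            except ConfigError as exc:
                errors.append(f"condition {label!r}: {exc}")
        else:
            missing = [k for k in _REAL_KEYS if k not in block]
            if missing:
                errors.append(f"condition {label!r}: missing paths {missing}")
                continue
            paths = {k: str(block[k]) for k in _REAL_KEYS}
            if "snp_mask" in block:
                paths["snp_mask"] = str(block["snp_mask"])
            conditions.append(ConditionSpec(label, paths=paths))
    if not conditions and not errors:
        errors.append("no conditions configured")
    baseline = str(raw.get("baseline", labels[0] if labels else ""))
    if labels and baseline not in labels:
        errors.append(f"baseline {baseline!r} not among conditions {labels}")
    if errors:
        raise ConfigError("; ".join(errors))
    return PipelineConfig(conditions=conditions, baseline=baseline,
                          filters=filters, outdir=str(raw.get("outdir", "editome_run")),
                          seed=seed, log_level=str(raw.get("log_level", "INFO")))


def _config_hash(raw: dict) -> str:
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sequential_attrition(calls: pd.DataFrame) -> dict[str, int]:
    """Telescoping attrition: each failed candidate is charged to its
    first failing filter, so candidates = passed + sum of failures."""
    out = {f"removed_{name}": 0 for name in FILTER_NAMES}
    for flags in calls.loc[~calls.passed, "flags"]:
        first = flags.split(",")[0]
        out[f"removed_{first}"] += 1
    out["candidates"] = int(len(calls))
    out["passed"] = int(calls.passed.sum())
    return out


def run_condition(spec: ConditionSpec, filters: FilterConfig,
                  outdir: Path) -> dict:
    """Process one condition; returns stage records for the report."""
    outdir.mkdir(parents=True, exist_ok=True)
    if spec.sim is not None:
        log.info("[%s] simulating dataset (seed %d)", spec.label, spec.sim.seed)
        paths = simulate_dataset(spec.sim, outdir / "sim")
        sam, ref = paths["sam"], paths["reference"]
        annotation_path, snp_mask = paths["bed"], paths["snp_mask"]
    else:
        sam, ref = spec.paths["sam"], spec.paths["reference"]
        annotation_path = spec.paths["annotation"]
        snp_mask = spec.paths.get("snp_mask")
        for name, p in list(spec.paths.items()):
            if not os.path.exists(p):
                raise ConfigError(
                    f"condition {spec.label!r}: {name} path {p!r} not found")

    log.info("[%s] building pileup", spec.label)
    pileup = build_pileup(sam, ref, filters)
    log.info("[%s] calling RDD sites over %d covered positions",
             spec.label, len(pileup))
    calls, warnings = call_rdd_sites(pileup, snp_mask, filters)
    for w in warnings:
        log.warning("[%s] %s", spec.label, w)

    annotation = GenomeAnnotation(eio.read_annotation(annotation_path))
    annotated = annotate_calls(calls[calls.passed], annotation)
    summary = summarize_editome(annotated, spec.label)

    write_calls_tsv(outdir / "calls.tsv", calls)
    contigs = {c: 10 ** 9 for c in calls.chrom.unique()} or {"none": 1}
    write_calls_vcf(outdir / "calls.vcf", calls, contigs)
    eio.write_tsv(outdir / "annotated.tsv", annotated)
    (outdir / "summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2))

    return {
        "label": spec.label,
        "n_reads_input": None,
        "n_pileup_positions": int(len(pileup)),
        "attrition": _sequential_attrition(calls),
        "summary": summary,
        "annotated": annotated,
    }


def run_pipeline(raw_config: dict, outdir: str | os.PathLike | None = None
                 ) -> dict:
    """Run the full pipeline from a raw config mapping.

    Returns the run report (also written to ``<outdir>/report.json``):
    per-condition record counts and attrition, per-condition editome
    summaries, baseline comparisons, and the config hash.
    """
    config = validate_config(raw_config)
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    results = {}
    for spec in config.conditions:
        results[spec.label] = run_condition(spec, config.filters,
                                            out / spec.label)

    base = results[config.baseline]["summary"]
    comparisons = {}
    for label, res in results.items():
        if label == config.baseline:
            continue
        comparisons[label] = compare_editomes(base, res["summary"]).to_dict()

    report = {
        "config_hash": _config_hash(raw_config),
        "seed": config.seed,
        "baseline": config.baseline,
        "conditions": {
            label: {
                "n_pileup_positions": res["n_pileup_positions"],
                "attrition": res["attrition"],
                "summary": res["summary"].to_dict(),
            } for label, res in results.items()},
        "comparisons": comparisons,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    log.info("report written to %s", out / "report.json")
    return report
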