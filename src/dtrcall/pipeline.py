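"""End-to-end orchestration: simulate -> coverage -> tagmap -> reconcile -> reopen.

The pipeline is driven by a declarative config (a nested dict, typically
loaded from YAML).  Given the same config and seed, two runs produce
byte-identical JSON reports; timestamps and environment details are kept
out of the report on purpose.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional

import numpy as np

from . import io
from .coverage import (
    CoverageProfile,
    NoRepeatCallError,
    call_terminal_repeat,
    detect_breakpoints,
    map_reads,
    profile_from_sam,
)
from .genome import GenomeInterval, Packaging, PhageGenome, Topology
from .mapping import SeedExtendMapper
from .reopen import reopen_genome
from .simulate import (
    DEFAULT_TAG,
    build_genome,
    ligate_tags,
    package_molecules,
    shotgun_reads,
)
from .tags import call_hotspots, find_tag_reads, map_junctions, reconcile_termini

__all__ = ["ConfigError", "default_config", "validate_config", "run_pipeline"]

REPORT_SCHEMA_VERSION = "1.0"


class ConfigError(ValueError):
    """Invalid pipeline configuration; lists every violation at once."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


def default_config() -> Dict:
    return {
        "seed": 0,
        "outdir": "dtrcall_run",
        "simulate": {
            "unit_length": 205_423,
            "repeat_length": 10_287,
            "gc": 0.662,
            "style": "nonpermuted_repeat",
            "imprecision_sd": 0.0,
            "n_molecules": 40,
            "coverage": 100.0,
            "mean_read_len": 400.0,
            "read_len_sd": 80.0,
            "error_rate": 0.0,
            "tag": DEFAULT_TAG,
            "n_tagged": 52,
            "termini_fraction": 0.37,
        },
        "inputs": {},               # fastq/assembly/sam paths; overrides simulate
        "detect": {"min_fold": 1.5, "window": 200},
        "hotspots": {"cluster_window": 5, "alpha": 0.05},
        "reconcile": {"tolerance": 5},
        "write_reads": False,       # FASTQ + truth TSV are large; opt in
    }


def _merge(base: Dict, override: Optional[Dict]) -> Dict:
    merged = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            merged[key] = _merge(base[key], value)
        else:
            merged[key] = value
    return merged


def validate_config(config: Optional[Dict]) -> Dict:
    """Merge with defaults and check every field, reporting all problems."""
    cfg = _merge(default_config(), config)
    problems: List[str] = []
    sim = cfg["simulate"]
    inputs = cfg["inputs"]
    if not isinstance(cfg["seed"], (int, np.integer)):
        problems.append(f"seed must be an integer, got {cfg['seed']!r}")
    if inputs:
        if "assembly" not in inputs:
            problems.append("inputs requires an 'assembly' FASTA path")
        if "fastq" not in inputs and "sam" not in inputs:
            problems.append("inputs requires 'fastq' reads or a 'sam' file")
        for key in ("assembly", "fastq", "sam", "tag_fastq"):
            path = inputs.get(key)
            if path and not os.path.exists(path):
                problems.append(f"inputs.{key}: no such file: {path}")
    else:
        if not 0 < sim["repeat_length"] < sim["unit_length"]:
            problems.append(
                "simulate: repeat_length must be in (0, unit_length), got "
                f"{sim['repeat_length']} vs {sim['unit_length']}"
            )
        if not 0 <= sim["gc"] <= 1:
            problems.append(f"simulate.gc must be in [0, 1], got {sim['gc']}")
        if sim["style"] not in {s.value for s in Packaging} - {"unknown"}:
            problems.append(f"simulate.style: unknown packaging style {sim['style']!r}")
        if sim["coverage"] <= 0:
            problems.append("simulate.coverage must be positive")
        if sim["mean_read_len"] < 50:
            problems.append("simulate.mean_read_len must be >= 50")
        if not 0 <= sim["error_rate"] < 1:
            problems.append("simulate.error_rate must be in [0, 1)")
        if len(sim["tag"]) < 20:
            problems.append("simulate.tag must be >= 20 nt")
    if cfg["detect"]["min_fold"] <= 1:
        problems.append("detect.min_fold must exceed 1")
    if cfg["detect"]["window"] < 10:
        problems.append("detect.window must be >= 10 bp")
    if not 0 < cfg["hotspots"]["alpha"] <= 1:
        problems.append("hotspots.alpha must be in (0, 1]")
    if problems:
        raise ConfigError(problems)
    return cfg


def run_pipeline(config: Optional[Dict] = None, outdir: Optional[str] = None) -> Dict:
    """Run the full terminus-mapping pipeline; returns the report dict.

    Artifacts (assembly FASTA, depth TSV/bedGraph, physical-genome FASTA
    with a repeat-annotation GFF3, report JSON) are written under the
    configured output directory.
    """
    cfg = validate_config(config)
    if outdir is not None:
        cfg["outdir"] = outdir
    out = io.ensure_dir(cfg["outdir"])
    master = np.random.SeedSequence(cfg["seed"])
    stage_seeds = [np.random.default_rng(s) for s in master.spawn(4)]

    if cfg["inputs"]:
        assembly = _load_assembly(cfg["inputs"]["assembly"])
        reads = (
            io.read_fastq(cfg["inputs"]["fastq"])
            if cfg["inputs"].get("fastq")
            else []
        )
        tag_read_pool = (
            io.read_fastq(cfg["inputs"]["tag_fastq"])
            if cfg["inputs"].get("tag_fastq")
            else reads
        )
        sam_path = cfg["inputs"].get("sam")
        tag = cfg["simulate"]["tag"]
    else:
        sim = cfg["simulate"]
        style = Packaging(sim["style"])
        assembly = build_genome(
            sim["unit_length"], sim["repeat_length"], sim["gc"], seed=stage_seeds[0]
        )
        molecules = package_molecules(
            assembly,
            n=sim["n_molecules"],
            style=style,
            imprecision_sd=sim["imprecision_sd"],
            seed=stage_seeds[1],
        )
        reads = shotgun_reads(
            molecules,
            mean_len=sim["mean_read_len"],
            len_sd=sim["read_len_sd"],
            fold_coverage=sim["coverage"],
            error_rate=sim["error_rate"],
            seed=stage_seeds[2],
            unit_length=assembly.unit_length,
        )
        tag = sim["tag"]
        tag_read_pool = ligate_tags(
            molecules,
            tag=tag,
            termini_fraction=sim["termini_fraction"],
            n_tagged=sim["n_tagged"],
            seed=stage_seeds[3],
            unit_length=assembly.unit_length,
        )
        io.write_fasta(
            os.path.join(out, "assembly.fasta"), [(assembly.name, assembly.sequence)]
        )
        if cfg["write_reads"]:
            io.write_fastq(
                os.path.join(out, "reads.fastq"),
                [(r.id, r.sequence, r.quality) for r in reads + tag_read_pool],
            )
            io.write_truth_tsv(
                os.path.join(out, "truth.tsv"), reads + tag_read_pool
            )
        sam_path = None

    mapper = SeedExtendMapper(assembly)
    if sam_path:
        profile = profile_from_sam(sam_path, assembly)
    else:
        if not reads:
            raise ConfigError(["no reads available for coverage analysis"])
        profile = map_reads(reads, assembly, mapper=mapper)
    io.write_depth_tsv(os.path.join(out, "depth.tsv"), profile.depths)
    io.write_bedgraph(os.path.join(out, "depth.bedgraph"), assembly.name, profile.depths)

    breakpoints = detect_breakpoints(
        profile,
        min_fold=cfg["detect"]["min_fold"],
        window=cfg["detect"]["window"],
    )
    repeat_call = None
    no_call_reason = None
    try:
        repeat_call = call_terminal_repeat(breakpoints, profile)
    except NoRepeatCallError as err:
        no_call_reason = str(err)

    tag_matches = find_tag_reads(tag_read_pool, tag) if tag_read_pool else []
    junctions = map_junctions(tag_matches, assembly, mapper=mapper)
    hotspots = (
        call_hotspots(
            junctions,
            assembly.unit_length,
            cluster_window=cfg["hotspots"]["cluster_window"],
            alpha=cfg["hotspots"]["alpha"],
        )
        if junctions
        else []
    )
    report_card = reconcile_termini(
        repeat_call,
        hotspots,
        assembly.unit_length,
        tolerance=cfg["reconcile"]["tolerance"],
    )

    physical = None
    if repeat_call is not None:
        physical = reopen_genome(assembly, repeat_call)
        io.write_fasta(
            os.path.join(out, "physical.fasta"), [(physical.name, physical.sequence)]
        )
        _write_physical_gff(out, physical)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": {
            "seed": int(cfg["seed"]),
            "detect": cfg["detect"],
            "hotspots": cfg["hotspots"],
            "reconcile": cfg["reconcile"],
            "simulate": None if cfg["inputs"] else cfg["simulate"],
            "inputs": cfg["inputs"] or None,
        },
        "coverage": {
            "total_reads": profile.total_reads,
            "unmapped_reads": profile.unmapped,
            "mean_depth": round(float(np.mean(profile.depths)), 3),
        },
        "breakpoints": [b.to_dict() for b in breakpoints],
        "repeat_call": repeat_call.to_dict() if repeat_call else None,
        "no_call_reason": no_call_reason,
        "tag_analysis": {
            "tag_reads": len(tag_matches),
            "junctions": len(junctions),
            "hotspots": [h.to_dict() for h in hotspots],
        },
        "reconciliation": report_card.to_dict(),
        "physical_genome": None
        if physical is None
        else {
            "length": len(physical.sequence),
            "repeat_length": physical.repeat_length,
            "rotation": physical.notes.get("rotation"),
            "right_end_approximate": bool(
                physical.notes.get("right_end_approximate", False)
            ),
        },
        "verdict": _overall_verdict(repeat_call, report_card),
    }
    with open(os.path.join(out, "report.json"), "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report


def _overall_verdict(repeat_call, report_card) -> str:
    if repeat_call is None:
        return (
            "no terminal repeat detected; packaging consistent with "
            "permuted/headful"
        )
    base = (
        f"non-permuted terminal repeat of {repeat_call.repeat_length} bp "
        f"({repeat_call.boundary_class} boundaries)"
    )
    return f"{base}; tag evidence: {report_card.verdict}"


def _load_assembly(path: str) -> PhageGenome:
    records = io.read_fasta(path)
    if len(records) != 1:
        raise ConfigError(
            [f"assembly FASTA must contain exactly one sequence, found {len(records)}"]
        )
    name, seq = records[0]
    return PhageGenome(
        name=name,
        sequence=seq,
        topology=Topology.CIRCULAR_ASSEMBLY,
        unit_length=len(seq),
    )


def _write_physical_gff(out: str, physical: PhageGenome) -> None:
    from .genome import GeneFeature

    rlen = physical.repeat_length
    total = len(physical.sequence)
    repeats = [
        GeneFeature(
            interval=GenomeInterval(0, rlen, "+"),
            kind="other",
            attributes={"ID": "terminal_repeat_left", "type": "repeat_region"},
        ),
        GeneFeature(
            interval=GenomeInterval(total - rlen, total, "+"),
            kind="other",
            attributes={"ID": "terminal_repeat_right", "type": "repeat_region"},
        ),
    ]
    io.write_gff3(os.path.join(out, "physical.gff3"), physical.name, total, repeats)
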