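"""Stage runner tying the modules into a pipeline.

`run_stage(name, config, params)` dispatches the same stages a shell
pipeline would expose — simulate, call-snv, call-cnv, call-sv,
build-profile, qc, lod-grid, metrics — as plain importable functions.
Every stage writes its primary outputs atomically (tmp file + rename) and
drops a run manifest (config + seed + package version) next to them, so
rerunning a stage with the same config and seed reproduces its outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .cnv import (NormalProfile, build_normal_profile, call_sample_cnvs,
                  corrected_coverage, read_counts_tsv, write_cnv_calls_tsv)
from .config import ConfigError, RunConfig
from .lod import concordance_r2, detection_grid, sensitivity, specificity
from .manifest import Manifest, read_manifest
from .pileup import read_pileup_tsv, write_pileup_tsv
from .qc import coverage_metrics, sample_qc
from .simulate import SimulationConfig, TruthVariant, simulate_pileup
from .snv import call_pileup
from .sv import (call_translocations, cluster_breakpoints, read_split_tsv,
                 write_evidence_audit, write_sv_calls_tsv)
from .vcf_io import write_vcf

STAGES = ("simulate", "call-snv", "call-cnv", "call-sv", "build-profile",
          "qc", "lod-grid", "metrics")


class StageError(RuntimeError):
    pass


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_run_manifest(out_dir: Path, stage: str, config: RunConfig) -> None:
    payload = {"stage": stage, "version": __version__, "seed": config.seed,
               "config": config.to_dict()}
    _atomic_write(out_dir / f"{stage}.manifest.json",
                  lambda p: Path(p).write_text(json.dumps(payload, indent=2) + "\n"))


def _require(params: dict, *keys) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise StageError(f"missing required parameter(s): {', '.join(missing)}")


def load_fasta(path) -> dict[str, str]:
    """Whole-contig FASTA load (panel references are small)."""
    with pysam.FastaFile(str(path)) as fa:
        return {name: fa.fetch(name) for name in fa.references}


def write_fasta(reference: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def run_stage(name: str, config: RunConfig, params: dict | None = None) -> dict:
    """Run one pipeline stage; returns a dict of output paths/objects.

    Raises :class:`StageError` on unknown stages or missing inputs and
    :class:`~panelcall.config.ConfigError` on invalid configuration.
    """
    if name not in STAGES:
        raise StageError(f"unknown stage {name!r}; choose from {', '.join(STAGES)}")
    config.validate()
    params = dict(params or {})
    out_dir = Path(params.pop("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    result = _DISPATCH[name](config, params, out_dir)
    _write_run_manifest(out_dir, name, config)
    return result


def _stage_simulate(config: RunConfig, params: dict, out_dir: Path) -> dict:
    sim = params.get("sim_config") or SimulationConfig(
        seed=config.seed, n_positions=200, depth_mean=800,
        truth_variants=(TruthVariant("chr1", 50, "T", 0.25),
                        TruthVariant("chr1", 120, "+AG", 0.15)))
    columns, reference, truth = simulate_pileup(sim)
    pileup_path = out_dir / "pileup.tsv"
    fasta_path = out_dir / "reference.fa"
    truth_path = out_dir / "truth.tsv"
    _atomic_write(pileup_path, lambda p: write_pileup_tsv(columns, p))
    _atomic_write(fasta_path, lambda p: write_fasta(reference, p))
    _atomic_write(truth_path, lambda p: pd.DataFrame(
        [{"chrom": t.chrom, "pos": t.pos + 1, "allele": t.allele, "vaf": t.vaf}
         for t in truth]).to_csv(p, sep="\t", index=False))
    return {"pileup": pileup_path, "reference": fasta_path, "truth": truth_path}


def _stage_call_snv(config: RunConfig, params: dict, out_dir: Path) -> dict:
    _require(params, "pileup")
    if not Path(params["pileup"]).exists():
        raise StageError(f"input not found: {params['pileup']}")
    columns = read_pileup_tsv(params["pileup"])
    reference = None
    if "reference" in params:
        reference = load_fasta(params["reference"])
    calls, nocalls = call_pileup(columns, reference=reference, config=config.snv)
    vcf_path = out_dir / "calls.vcf"
    _atomic_write(vcf_path, lambda p: write_vcf(calls, p, reference=reference))
    return {"vcf": vcf_path, "calls": calls, "nocalls": nocalls}


def _stage_build_profile(config: RunConfig, params: dict, out_dir: Path) -> dict:
    _require(params, "manifest", "counts")
    manifest = read_manifest(params["manifest"])
    vectors = [read_counts_tsv(p, manifest, sample_id=str(i))
               for i, p in enumerate(params["counts"])]
    matrix = np.vstack([corrected_coverage(v, manifest, config.cnv) for v in vectors])
    profile = build_normal_profile(matrix, [r.region_id for r in manifest], config.cnv)
    path = out_dir / "normal_profile.tsv"
    _atomic_write(path, profile.write_tsv)
    return {"profile": path, "profile_obj": profile}


def _stage_call_cnv(config: RunConfig, params: dict, out_dir: Path) -> dict:
    _require(params, "manifest", "counts", "profile")
    manifest = read_manifest(params["manifest"])
    vector = read_counts_tsv(params["counts"], manifest, sample_id="tumor")
    profile = params["profile"]
    if not isinstance(profile, NormalProfile):
        df = pd.read_csv(profile, sep="\t")
        profile = NormalProfile(list(df["region_id"]), df["mean"].to_numpy(),
                                df["sd"].to_numpy(), int(df["n"].iloc[0]), 0,
                                config.cnv.z_cutoff, config.cnv.deviant_region_fraction,
                                config.cnv.sd_floor_fraction)
    calls = call_sample_cnvs(vector, manifest, profile, config.cnv)
    path = out_dir / "cnv_calls.tsv"
    _atomic_write(path, lambda p: write_cnv_calls_tsv(calls, p))
    return {"cnv_calls": path, "calls": calls}


def _stage_call_sv(config: RunConfig, params: dict, out_dir: Path) -> dict:
    _require(params, "manifest", "splits")
    manifest = read_manifest(params["manifest"])
    evidence = params["splits"]
    if not isinstance(evidence, list):
        evidence = read_split_tsv(evidence)
    clusters = cluster_breakpoints(evidence, manifest, config.sv)
    calls = call_translocations(clusters, params.get("known_partners", ()), config.sv)
    calls_path = out_dir / "sv_calls.tsv"
    audit_path = out_dir / "sv_evidence.tsv"
    _atomic_write(calls_path, lambda p: write_sv_calls_tsv(calls, p))
    _atomic_write(audit_path, lambda p: write_evidence_audit(clusters, p))
    return {"sv_calls": calls_path, "audit": audit_path, "calls": calls}


def _stage_qc(config: RunConfig, params: dict, out_dir: Path) -> dict:
    _require(params, "depths", "calls")
    report = coverage_metrics(params["depths"],
                              total_reads=params.get("total_reads"),
                              on_target_reads=params.get("on_target_reads"),
                              duplicate_fraction=params.get("duplicate_fraction"))
    sample_qc(report, calls=params["calls"], config=config.qc)
    path = out_dir / "qc.json"
    _atomic_write(path, lambda p: Path(p).write_text(report.to_json() + "\n"))
    return {"qc": path, "report": report}


def _stage_lod_grid(config: RunConfig, params: dict, out_dir: Path) -> dict:
    _require(params, "source_factory", "coverages", "vafs")
    grid = detection_grid(params["source_factory"], params["coverages"],
                          params["vafs"], params.get("replicates", config.lod.replicates),
                          config=config.snv, seed=config.seed,
                          reference=params.get("reference"))
    tsv = out_dir / "lod_grid.tsv"
    js = out_dir / "lod_grid.json"
    _atomic_write(tsv, grid.write_tsv)
    _atomic_write(js, grid.write_json)
    return {"grid_tsv": tsv, "grid_json": js, "grid": grid}


def _stage_metrics(config: RunConfig, params: dict, out_dir: Path) -> dict:
    out: dict = {}
    if "truth" in params and "called" in params:
        out["sensitivity"] = sensitivity(params["truth"], params["called"])
    if "n_assessed" in params:
        out["specificity"] = specificity(params["n_assessed"],
                                         params.get("n_false_positive", 0))
    if "sr_x" in params and "sr_y" in params:
        out["concordance_r2"] = concordance_r2(params["sr_x"], params["sr_y"])
    path = out_dir / "metrics.json"
    _atomic_write(path, lambda p: Path(p).write_text(json.dumps(out, indent=2) + "\n"))
    return {"metrics": path, **out}


_DISPATCH = {
    "simulate": _stage_simulate,
    "call-snv": _stage_call_snv,
    "call-cnv": _stage_call_cnv,
    "call-sv": _stage_call_sv,
    "build-profile": _stage_build_profile,
    "qc": _stage_qc,
    "lod-grid": _stage_lod_grid,
    "metrics": _stage_metrics,
}
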