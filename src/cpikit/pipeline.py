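"""Orchestration: curate -> consensus/motif -> physchem -> phylogeny (-> interactions).

Produces a deterministic report bundle of TSV/text outputs plus a JSON run
log with versions, seed and per-stage timings. Any stage failure aborts with
the failing stage named; a missing optional input (PDB) merely disables its
stage.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import cpikit
from cpikit.conservation import (
    DEFAULT_THRESHOLDS, consensus_profile, derive_spacing_motif,
    read_alignment_fasta, write_consensus_tsv, write_frequencies_tsv,
)
from cpikit.curation import curate, trim_to_mature
from cpikit.interactions import (
    GeometryParams, detect_interactions, parse_structure, write_interactions_tsv,
)
from cpikit.motif import motif_match_rate
from cpikit.physchem import physchem_table, write_panel_tsv
from cpikit.phylogeny import bootstrap_supports, write_newick, write_supports_tsv
from cpikit.records import read_fasta, write_fasta


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    fasta: str
    aln: str
    outdir: str
    pdb: str | None = None
    chain_a: str | None = None
    chain_b: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    min_cys: int = 5
    anchor_threshold: float = 90.0
    correction: str = "kimura"
    reps: int = 100
    seed: int = 17
    geometry: GeometryParams = field(default_factory=GeometryParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "thresholds" in raw:
            raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
        if "geometry" in raw:
            raw["geometry"] = GeometryParams(**raw["geometry"])
        return cls(**raw)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run all configured stages; returns a map of output name -> path."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                return False
        return _Stage()

    with stage("curate"):
        records = read_fasta(cfg.fasta)
        report = curate(records, min_cys=cfg.min_cys)
        outputs["kept"] = outdir / "kept.fasta"
        write_fasta(report.kept, outputs["kept"])
        outputs["rejected"] = outdir / "rejected.tsv"
        report.write_tsv(outputs["rejected"])

    with stage("consensus"):
        aln = read_alignment_fasta(cfg.aln)
        profile = consensus_profile(aln, cfg.thresholds)
        outputs["consensus"] = outdir / "consensus.tsv"
        write_consensus_tsv(profile, outputs["consensus"])
        outputs["freqs"] = outdir / "freqs.tsv"
        write_frequencies_tsv(profile, outputs["freqs"])

    with stage("motif"):
        motif = derive_spacing_motif(aln, cfg.anchor_threshold)
        outputs["motif"] = outdir / "motif.txt"
        outputs["motif"].write_text(f"{motif.compact}\n{motif.prosite}\n")
        trimmed = [trim_to_mature(r, motif) for r in report.kept]
        rate = motif_match_rate(trimmed, motif)
        outputs["match_rate"] = outdir / "match_rate.txt"
        outputs["match_rate"].write_text(f"{rate:.1f}\n")

    with stage("physchem"):
        panels = physchem_table(trimmed)
        outputs["panel"] = outdir / "panel.tsv"
        write_panel_tsv(panels, outputs["panel"])

    with stage("phylogeny"):
        tree = bootstrap_supports(aln, cfg.reps, cfg.seed, cfg.correction)
        outputs["tree"] = outdir / "tree.nwk"
        outputs["tree"].write_text(write_newick(tree) + "\n")
        outputs["supports"] = outdir / "supports.tsv"
        write_supports_tsv(tree, outputs["supports"])

    if cfg.pdb:
        with stage("interactions"):
            model = parse_structure(cfg.pdb)
            contacts = detect_interactions(model, cfg.chain_a, cfg.chain_b,
                                           cfg.geometry)
            outputs["interactions"] = outdir / "interactions.tsv"
            write_interactions_tsv(contacts, outputs["interactions"])

    log = {
        "cpikit_version": cpikit.__version__,
        "python_version": platform.python_version(),
        "seed": cfg.seed,
        "config": {
            "fasta": cfg.fasta, "aln": cfg.aln, "pdb": cfg.pdb,
            "chain_a": cfg.chain_a, "chain_b": cfg.chain_b,
            "thresholds": list(cfg.thresholds), "min_cys": cfg.min_cys,
            "anchor_threshold": cfg.anchor_threshold,
            "correction": cfg.correction, "reps": cfg.reps,
        },
        "stage_timings_s": timings,
        "outputs": {name: str(path) for name, path in outputs.items()},
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    outputs["log"] = log_path
    return outputs
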