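"""End-to-end orchestration: simulate -> align -> call sites -> test ->
target switch -> motif, driven by one declarative config.

Every run writes a manifest (parameters, input checksums, seed, per-stage
record counts) so identical configs produce identical, checkable outputs.
Randomness enters only through the explicit seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align_count import AlignmentParams, align_and_count
from .differential import differential_editing
from .editing_sites import SiteFilterParams, build_matrix, call_sites
from .io_formats import (
    read_fasta,
    read_fastq,
    read_hairpins,
    read_mature_table,
    read_table,
    write_table,
)
from .motif_context import motif_table
from .simulate import PlantedSite, SimConfig, simulate_utrs, write_simulation
from .target_switch import target_switch_analysis

SCHEMA_VERSION = "1"

log = logging.getLogger("miredit")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[miredit:%(stage)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _stage_log(stage: str, message: str) -> None:
    log.info(message, extra={"stage": stage})


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    outdir: str = "miredit-run"
    rng_seed: int = 0
    alpha: float = 0.05
    simulate: SimConfig | None = None
    hairpins: str | None = None  # FASTA; required unless simulating
    mature: str | None = None  # TSV; required unless simulating
    reads: dict[str, str] = field(default_factory=dict)  # sample_id -> FASTQ
    design: str | None = None  # TSV; required unless simulating
    utrs: str | None = None  # FASTA of 3'UTRs; synthetic if absent
    n_synthetic_utrs: int = 200
    synthetic_utr_length: int = 600
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    site_filters: SiteFilterParams = field(default_factory=SiteFilterParams)
    motif_enrichment: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "simulate" in kwargs and kwargs["simulate"] is not None:
            sim = dict(kwargs["simulate"])
            if "planted_sites" in sim:
                sim["planted_sites"] = [
                    PlantedSite(**s) if isinstance(s, dict) else PlantedSite(*s)
                    for s in sim["planted_sites"]
                ]
            if "group_sizes" in sim:
                sim["group_sizes"] = tuple(sim["group_sizes"])
            kwargs["simulate"] = SimConfig(**sim)
        if "alignment" in kwargs and kwargs["alignment"] is not None:
            kwargs["alignment"] = AlignmentParams(**kwargs["alignment"])
        if "site_filters" in kwargs and kwargs["site_filters"] is not None:
            kwargs["site_filters"] = SiteFilterParams(**kwargs["site_filters"])
        return cls(**kwargs)

    def validate_inputs(self) -> None:
        """Fail before any compute when a referenced input is missing."""
        if self.simulate is None:
            required = {"hairpins": self.hairpins, "mature": self.mature,
                        "design": self.design}
            for name, path in required.items():
                if path is None:
                    raise FileNotFoundError(f"config is missing input {name!r}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")
            if not self.reads:
                raise FileNotFoundError("config lists no read files")
            for sample, path in self.reads.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"reads for {sample!r} not found: {path}")
        if self.utrs is not None and not Path(self.utrs).exists():
            raise FileNotFoundError(f"UTR file not found: {self.utrs}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "rng_seed": config.rng_seed,
        "alpha": config.alpha,
        "alignment": asdict(config.alignment),
        "site_filters": asdict(config.site_filters),
        "stages": {},
        "checksums": {},
    }

    # -- stage: simulate or load inputs ------------------------------------
    if config.simulate is not None:
        _stage_log("simulate", "generating synthetic reference and reads")
        sim = config.simulate
        manifest["simulate"] = {
            **{k: v for k, v in asdict(sim).items() if k != "planted_sites"},
            "planted_sites": [asdict(s) for s in sim.planted_sites],
        }
        simdir = outdir / "simulated"
        files, truth = write_simulation(sim, simdir)
        hairpins_path, mature_path = files["hairpins"], files["mature"]
        design_path = files["design"]
        reads_paths = {
            k.split(":", 1)[1]: v for k, v in files.items() if k.startswith("reads:")
        }
        manifest["stages"]["simulate"] = {
            "n_samples": len(reads_paths),
            "n_hairpins": sim.n_hairpins + (1 if sim.include_mir376a else 0),
            "total_reads": int(truth.counts["total_reads"].sum()),
        }
    else:
        hairpins_path, mature_path = Path(config.hairpins), Path(config.mature)
        design_path = Path(config.design)
        reads_paths = {k: Path(v) for k, v in config.reads.items()}

    for name, path in [("hairpins", hairpins_path), ("mature", mature_path),
                       ("design", design_path)]:
        manifest["checksums"][name] = _sha256(Path(path))

    hairpins = read_hairpins(hairpins_path)
    annotations = read_mature_table(mature_path, hairpins)
    design = read_table(design_path, "design")

    # -- stage: align ------------------------------------------------------
    _stage_log("align", f"aligning {len(reads_paths)} samples")
    reads_by_sample = {s: read_fastq(p) for s, p in sorted(reads_paths.items())}
    counts, align_summary = align_and_count(
        reads_by_sample, hairpins, annotations, config.alignment
    )
    write_table(counts, outdir / "counts.tsv", "counts")
    align_summary.to_csv(outdir / "align_summary.tsv", sep="\t", index=False)
    manifest["stages"]["align"] = {
        "n_count_rows": len(counts),
        "assigned_reads": int(align_summary["assigned"].sum()),
    }

    # -- stage: call sites -------------------------------------------------
    _stage_log("call-sites", "calling A->G editing sites")
    sites, diagnostics = call_sites(counts, config.site_filters)
    write_table(sites, outdir / "sites.tsv", "sites")
    diagnostics.to_csv(outdir / "mismatch_diagnostics.tsv", sep="\t", index=False)
    matrix = build_matrix(sites, design)
    write_table(matrix.to_table(), outdir / "matrix.tsv", "matrix")
    manifest["stages"]["call_sites"] = {"n_sites": len(matrix.sites)}

    # -- stage: differential -----------------------------------------------
    _stage_log("diff-edit", "testing differential editing")
    results = differential_editing(matrix, design, config.alpha)
    write_table(results, outdir / "differential.tsv", "differential")
    n_sig = int(results["significant"].sum()) if len(results) else 0
    manifest["stages"]["differential"] = {
        "n_tested": int(results["testable"].sum()) if len(results) else 0,
        "n_significant": n_sig,
    }

    # -- stage: target switch ----------------------------------------------
    sig = results[results["significant"]] if len(results) else results
    if len(sig):
        top = sig.sort_values("p_bh").iloc[0]
        ann = {a.mature_id: a for a in annotations}[top["mature_id"]]
        hp = hairpins[ann.hairpin_id].sequence
        mature_seq = hp[ann.start - 1 : ann.end]
        if config.utrs is not None:
            utrs = read_fasta(config.utrs)
        else:
            _stage_log("target-switch", "no UTR set supplied; using synthetic UTRs")
            utrs = simulate_utrs(
                config.n_synthetic_utrs, config.synthetic_utr_length,
                rng_seed=config.rng_seed + 7,
            )
        _stage_log(
            "target-switch",
            f"comparing target pools for {top['mature_id']}(+{int(top['position'])})",
        )
        match_table, comparison = target_switch_analysis(
            top["mature_id"], mature_seq, int(top["position"]), utrs
        )
        write_table(match_table, outdir / "site_matches.tsv", "site_matches")
        write_table(
            comparison.to_table(), outdir / "pool_comparison.tsv", "pool_comparison"
        )
        manifest["stages"]["target_switch"] = {
            "site": f"{top['mature_id']}:{int(top['position'])}",
            "n_shared": comparison.n_shared,
            "shared_fraction": comparison.shared_fraction,
        }
    else:
        _stage_log("target-switch", "no significant site; stage skipped")
        manifest["stages"]["target_switch"] = {"site": None}

    # -- stage: motif -------------------------------------------------------
    _stage_log("motif", "tabulating trinucleotide contexts")
    motifs = motif_table(
        sites, hairpins, annotations, with_enrichment=config.motif_enrichment
    )
    write_table(motifs, outdir / "motifs.tsv", "motif_counts")
    manifest["stages"]["motif"] = {
        "top_motif": motifs.iloc[0]["trinucleotide"] if len(motifs) else None
    }

    for out_name in ["counts.tsv", "sites.tsv", "matrix.tsv", "differential.tsv",
                     "motifs.tsv"]:
        p = outdir / out_name
        if p.exists():
            manifest["checksums"][out_name] = _sha256(p)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _stage_log("run", f"complete; manifest at {outdir / 'manifest.json'}")
    return manifest
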