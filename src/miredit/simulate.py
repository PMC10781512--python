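"""Synthetic small RNA-seq generator with planted A-to-I editing.

Emulates a two-group hippocampal small RNA-seq design: by default 8 control
and 16 patient libraries, per-miRNA coverage drawn from a negative binomial,
one planted seed-editing site whose per-read editing probability differs
between groups (0.85 vs 0.79), and uniform per-base sequencing errors at
rate 0.01. Edits are planted in a 5'-UAG-3' context, the trinucleotide
preferred by ADAR enzymes, so the motif analysis sees a realistic substrate.

Two generation routes are provided:

* :func:`simulate_reads` writes per-read FASTQ libraries and exercises the
  whole pipeline including adapter trimming and alignment;
* :func:`simulate_position_counts` draws the per-position base tallies
  directly from the same generative model (the counts are the sufficient
  statistics of the read-level model for full-length reads), which is the
  fast route for power and false-discovery studies over many replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._sequences import MIR376A_3P_UNEDITED, RNA_BASES
from .io_formats import (
    HairpinRecord,
    MatureAnnotation,
    ReadRecord,
    write_fasta,
    write_fastq,
    write_mature_table,
    write_table,
)

_BASES = np.array(list(RNA_BASES))
_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}


@dataclass(frozen=True)
class PlantedSite:
    """A planted editing site: mature position with per-group edit fractions."""

    mature_id: str
    position: int
    fraction_control: float
    fraction_case: float


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    Defaults mirror the modelled cohort: 8 controls vs 16 cases, ~21-nt
    matures, deep coverage, a single site edited at 0.85 (control) vs 0.79
    (case) planted among otherwise unedited miRNAs, and a uniform per-base
    sequencing error rate of 0.01.
    """

    n_hairpins: int = 51
    mature_length: int = 21
    group_sizes: tuple[int, int] = (8, 16)
    coverage_mean: float = 2000.0
    coverage_dispersion: float = 10.0
    planted_sites: Sequence[PlantedSite] = field(
        default_factory=lambda: (PlantedSite("sim-mir-001-3p", 6, 0.85, 0.79),)
    )
    planted_context: str | None = "UAG"
    error_rate: float = 0.01
    adapter: str | None = None
    end_jitter: bool = False
    include_mir376a: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hairpins < 1:
            raise ValueError("n_hairpins must be >= 1")
        if self.mature_length < 15:
            raise ValueError("mature_length must be >= 15")
        if min(self.group_sizes) < 2:
            raise ValueError("each group needs >= 2 samples")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        for site in self.planted_sites:
            if not (1 <= site.position <= self.mature_length):
                raise ValueError(
                    f"planted position {site.position} outside the mature span"
                )
            for f in (site.fraction_control, site.fraction_case):
                if not (0.0 <= f <= 1.0):
                    raise ValueError("editing fractions must be in [0, 1]")
        if self.planted_context is not None:
            if len(self.planted_context) != 3 or self.planted_context[1] != "A":
                raise ValueError("planted_context must be a trinucleotide X-A-Z")

    @property
    def sample_ids(self) -> list[str]:
        n_ctrl, n_case = self.group_sizes
        return [f"ctrl-{i+1:02d}" for i in range(n_ctrl)] + [
            f"case-{i+1:02d}" for i in range(n_case)
        ]

    @property
    def design(self) -> pd.DataFrame:
        n_ctrl, n_case = self.group_sizes
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": ["control"] * n_ctrl + ["case"] * n_case,
            }
        )


def mature_name(i: int) -> str:
    return f"sim-mir-{i:03d}-3p"


def hairpin_name(i: int) -> str:
    return f"sim-mir-{i:03d}"


@dataclass
class GroundTruth:
    """True per-sample read counts and per-site edited counts."""

    counts: pd.DataFrame  # sample_id, mature_id, total_reads
    sites: pd.DataFrame  # sample_id, mature_id, position, edited_reads, ...

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        write_table(self.counts, outdir / "ground_truth_counts.tsv", "ground_truth_counts")
        write_table(self.sites, outdir / "ground_truth_sites.tsv", "ground_truth_sites")


def simulate_reference(
    config: SimConfig,
) -> tuple[dict[str, HairpinRecord], list[MatureAnnotation]]:
    """Generate hairpins each carrying one mature arm on the 3p side.

    Every hairpin is 5p-arm + loop + 3p-mature; planted positions always
    carry the reference base A (inside the configured context) so an A->G
    edit is well defined. Deterministic given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    loop_len = 12
    planted_by_mature: dict[str, list[PlantedSite]] = {}
    for site in config.planted_sites:
        planted_by_mature.setdefault(site.mature_id, []).append(site)

    hairpins: dict[str, HairpinRecord] = {}
    annotations: list[MatureAnnotation] = []
    for i in range(1, config.n_hairpins + 1):
        mid, hid = mature_name(i), hairpin_name(i)
        mature = rng.choice(_BASES, size=config.mature_length).tolist()
        for site in planted_by_mature.get(mid, []):
            pos0 = site.position - 1
            if config.planted_context is not None:
                ctx = config.planted_context
                if pos0 - 1 >= 0:
                    mature[pos0 - 1] = ctx[0]
                mature[pos0] = "A"
                if pos0 + 1 < len(mature):
                    mature[pos0 + 1] = ctx[2]
            else:
                mature[pos0] = "A"
        mature_seq = "".join(mature)
        arm5 = "".join(rng.choice(_BASES, size=config.mature_length))
        loop = "".join(rng.choice(_BASES, size=loop_len))
        hairpin_seq = arm5 + loop + mature_seq
        start = len(arm5) + loop_len + 1
        hairpins[hid] = HairpinRecord(hid, hairpin_seq)
        annotations.append(
            MatureAnnotation(mid, hid, start, start + config.mature_length - 1, "3p")
        )

    if config.include_mir376a:
        mature_seq = MIR376A_3P_UNEDITED
        arm5 = "".join(rng.choice(_BASES, size=len(mature_seq)))
        loop = "".join(rng.choice(_BASES, size=loop_len))
        hid, mid = "hsa-mir-376a", "hsa-miR-376a-3p"
        hairpins[hid] = HairpinRecord(hid, arm5 + loop + mature_seq)
        start = len(arm5) + loop_len + 1
        annotations.append(
            MatureAnnotation(mid, hid, start, start + len(mature_seq) - 1, "3p")
        )
    return hairpins, annotations


def _draw_coverage(config: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Per-miRNA per-sample read counts ~ negative binomial."""
    r = config.coverage_dispersion
    if not math.isfinite(r) or r <= 0:
        return rng.poisson(config.coverage_mean, size=size)
    p = r / (r + config.coverage_mean)
    return rng.negative_binomial(r, p, size=size)


def _group_fraction(site: PlantedSite, group: str) -> float:
    return site.fraction_control if group == "control" else site.fraction_case


def simulate_reads(
    config: SimConfig,
    reference: tuple[dict[str, HairpinRecord], list[MatureAnnotation]] | None = None,
) -> tuple[dict[str, list[ReadRecord]], GroundTruth]:
    """Draw per-sample read sets from the generative model.

    Each read starts as the full-length mature sequence, is edited at every
    planted site with its group's fraction (independent Bernoulli per read),
    then passed through uniform per-base substitution errors, optional
    ±1-nt end jitter and an optional 3' adapter suffix.
    """
    if reference is None:
        reference = simulate_reference(config)
    hairpins, annotations = reference
    ann_by_mature = {a.mature_id: a for a in annotations}
    planted_by_mature: dict[str, list[PlantedSite]] = {}
    for site in config.planted_sites:
        if site.mature_id not in ann_by_mature:
            raise ValueError(f"planted site on unknown mature {site.mature_id!r}")
        planted_by_mature.setdefault(site.mature_id, []).append(site)

    rng = np.random.default_rng(config.rng_seed + 1)
    design = config.design
    reads_by_sample: dict[str, list[ReadRecord]] = {}
    truth_counts, truth_sites = [], []

    for sample_id, group in design.itertuples(index=False):
        reads: list[ReadRecord] = []
        for ann in annotations:
            hp = hairpins[ann.hairpin_id].sequence
            mature = hp[ann.start - 1 : ann.end]
            n = int(_draw_coverage(config, rng, 1)[0])
            base_matrix = np.tile(np.array(list(mature)), (n, 1)) if n else None
            for site in planted_by_mature.get(ann.mature_id, []):
                f = _group_fraction(site, group)
                edited = rng.random(n) < f
                if n:
                    base_matrix[edited, site.position - 1] = "G"
                truth_sites.append(
                    (sample_id, ann.mature_id, site.position, int(edited.sum()), n,
                     group, f)
                )
            if n:
                if config.error_rate > 0:
                    err = rng.random(base_matrix.shape) < config.error_rate
                    if err.any():
                        # substitute uniformly among the three other bases
                        shift = rng.integers(1, 4, size=int(err.sum()))
                        idx = np.array(
                            [_BASE_INDEX[b] for b in base_matrix[err]], dtype=int
                        )
                        base_matrix[err] = _BASES[(idx + shift) % 4]
                for j in range(n):
                    seq = "".join(base_matrix[j])
                    if config.end_jitter:
                        jit = rng.integers(-1, 2)
                        if jit == -1:
                            seq = seq[1:]
                        elif jit == 1:
                            seq = seq + hp[ann.end] if ann.end < len(hp) else seq
                    if config.adapter:
                        seq = seq + config.adapter
                    reads.append(
                        ReadRecord(f"{ann.mature_id}|{sample_id}|{j+1}", seq)
                    )
            truth_counts.append((sample_id, ann.mature_id, n))
        reads_by_sample[sample_id] = reads

    truth = GroundTruth(
        counts=pd.DataFrame(
            truth_counts, columns=["sample_id", "mature_id", "total_reads"]
        ),
        sites=pd.DataFrame(
            truth_sites,
            columns=[
                "sample_id", "mature_id", "position", "edited_reads",
                "total_reads", "group", "true_fraction",
            ],
        ),
    )
    return reads_by_sample, truth


def observed_base_probabilities(
    ref_base: str, edit_fraction: float, error_rate: float
) -> dict[str, float]:
    """Marginal probability of observing each base at one read position.

    The true base is the reference, switched to G with ``edit_fraction``
    when the position is an editing site; sequencing then reports the true
    base with probability 1-e and each of the other three with e/3.
    """
    e = error_rate
    probs = {b: e / 3.0 for b in RNA_BASES}
    if edit_fraction > 0 and ref_base == "A":
        probs["A"] = (1 - edit_fraction) * (1 - e) + edit_fraction * e / 3.0
        probs["G"] = edit_fraction * (1 - e) + (1 - edit_fraction) * e / 3.0
    else:
        probs[ref_base] = 1 - e
    return probs


def _observe_pool(
    rng: np.random.Generator, n: np.ndarray, true_base: str, error_rate: float
) -> np.ndarray:
    """Observed base tallies for pools of reads whose true base is known.

    Multinomial draw (true base with 1-e, each other base e/3) realized as
    stick-breaking conditional binomials, vectorized over samples. Returns a
    (4, n_samples) array ordered A, C, G, U.
    """
    n = np.asarray(n, dtype=np.int64)
    counts = np.zeros((4, n.shape[0]), dtype=np.int64)
    if error_rate == 0.0:
        counts[_BASE_INDEX[true_base]] = n
        return counts
    probs = np.full(4, error_rate / 3.0)
    probs[_BASE_INDEX[true_base]] = 1.0 - error_rate
    remaining = n.copy()
    remaining_p = 1.0
    for b_idx in range(3):
        cond = min(max(probs[b_idx] / remaining_p, 0.0), 1.0)
        draw = rng.binomial(remaining, cond)
        counts[b_idx] = draw
        remaining = remaining - draw
        remaining_p -= probs[b_idx]
    counts[3] = remaining
    return counts


def simulate_position_counts(
    config: SimConfig,
    reference: tuple[dict[str, HairpinRecord], list[MatureAnnotation]] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw per-position base tallies directly (fast route, same model).

    For full-length reads the per-position multinomial counts are the
    sufficient statistics of the read-level model, so this produces tallies
    distributed identically to aligning :func:`simulate_reads` output, at a
    fraction of the cost. Returns a counts table in the ``counts`` schema.
    """
    if reference is None:
        reference = simulate_reference(config)
    hairpins, annotations = reference
    planted = {
        (s.mature_id, s.position): s for s in config.planted_sites
    }
    rng = np.random.default_rng(config.rng_seed + 1)
    design = config.design
    groups = design["group"].to_numpy()
    samples = design["sample_id"].to_numpy()
    n_samples = len(samples)

    rows = []
    truth_counts, truth_sites = [], []
    for ann in annotations:
        hp = hairpins[ann.hairpin_id].sequence
        mature = hp[ann.start - 1 : ann.end]
        cov = _draw_coverage(config, rng, n_samples)
        for s_idx in range(n_samples):
            truth_counts.append((samples[s_idx], ann.mature_id, int(cov[s_idx])))
        for pos in range(1, len(mature) + 1):
            ref_base = mature[pos - 1]
            site = planted.get((ann.mature_id, pos))
            if site is not None:
                # draw the true edited count first, then sequencing errors
                # conditional on it: with error_rate=0 the observed G tally
                # equals the ground-truth edited count exactly
                fractions = np.where(
                    groups == "control", site.fraction_control, site.fraction_case
                )
                edited = rng.binomial(cov, fractions)
                for s_idx in range(n_samples):
                    truth_sites.append(
                        (samples[s_idx], ann.mature_id, pos, int(edited[s_idx]),
                         int(cov[s_idx]), groups[s_idx], float(fractions[s_idx]))
                    )
                base_counts = _observe_pool(rng, edited, "G", config.error_rate)
                base_counts += _observe_pool(
                    rng, cov - edited, ref_base, config.error_rate
                )
            else:
                base_counts = _observe_pool(rng, cov, ref_base, config.error_rate)
            for s_idx in range(n_samples):
                rows.append(
                    (
                        samples[s_idx], ann.mature_id, pos, ref_base,
                        base_counts[0, s_idx], base_counts[1, s_idx],
                        base_counts[2, s_idx], base_counts[3, s_idx],
                    )
                )
    counts = pd.DataFrame(
        rows,
        columns=["sample_id", "mature_id", "position", "ref_base", "A", "C", "G", "U"],
    )
    truth = GroundTruth(
        counts=pd.DataFrame(
            truth_counts, columns=["sample_id", "mature_id", "total_reads"]
        ),
        sites=pd.DataFrame(
            truth_sites,
            columns=[
                "sample_id", "mature_id", "position", "edited_reads",
                "total_reads", "group", "true_fraction",
            ],
        ),
    )
    return counts, truth


def simulate_utrs(
    n_utrs: int,
    length: int,
    rng_seed: int = 0,
    planted_patterns: Mapping[str, Sequence[str]] | None = None,
) -> list[tuple[str, str]]:
    """Random 3'UTR sequences with optional planted target-site patterns.

    ``planted_patterns`` maps utr_id -> list of site strings inserted at
    distinct random positions of that UTR.
    """
    rng = np.random.default_rng(rng_seed)
    utrs = []
    planted_patterns = planted_patterns or {}
    for i in range(1, n_utrs + 1):
        uid = f"utr-{i:04d}"
        seq = rng.choice(_BASES, size=length)
        for j, pattern in enumerate(planted_patterns.get(uid, [])):
            start = 10 + j * (len(pattern) + 10)
            if start + len(pattern) > length:
                raise ValueError(f"UTR {uid} too short for planted patterns")
            seq[start : start + len(pattern)] = list(pattern)
        utrs.append((uid, "".join(seq)))
    return utrs


def write_simulation(
    config: SimConfig, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Run the read-level simulation and write all artifacts to ``outdir``.

    Emits reference FASTA, mature TSV, one FASTQ per sample, the design
    table and the ground-truth tables. Returns the file manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    hairpins, annotations = reference
    reads_by_sample, truth = simulate_reads(config, reference)

    files: dict[str, Path] = {}
    files["hairpins"] = outdir / "hairpins.fa"
    write_fasta(((h.id, h.sequence) for h in hairpins.values()), files["hairpins"])
    files["mature"] = outdir / "mature.tsv"
    write_mature_table(annotations, files["mature"])
    files["design"] = outdir / "design.tsv"
    write_table(config.design, files["design"], "design")
    for sample_id, reads in reads_by_sample.items():
        p = outdir / f"{sample_id}.fastq"
        write_fastq(reads, p)
        files[f"reads:{sample_id}"] = p
    truth.write(outdir)
    files["ground_truth_counts"] = outdir / "ground_truth_counts.tsv"
    files["ground_truth_sites"] = outdir / "ground_truth_sites.tsv"
    return files, truth
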