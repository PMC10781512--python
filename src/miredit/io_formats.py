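"""Readers and writers for the pipeline's on-disk artifacts.

FASTA holds hairpin references and 3'UTR sets, FASTQ holds per-sample small
RNA reads (plain or gzip), and all tabular results are tab-separated files
with declared headers. Sequences are normalized to the upper-case RNA
alphabet on read; coordinates are 1-based inclusive on the 5'->3' strand.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._sequences import normalize_sequence

RNA_ALPHABET = frozenset("ACGU")


class FormatError(ValueError):
    """Raised for malformed input files or schema violations."""


@dataclass(frozen=True)
class HairpinRecord:
    """A miRNA stem-loop (precursor) sequence, miRBase style."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("hairpin record with empty id")
        if not self.sequence:
            raise FormatError(f"hairpin {self.id!r} has an empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"hairpin {self.id!r} contains non-ACGU characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """Location of a mature miRNA arm on its hairpin (1-based inclusive)."""

    mature_id: str
    hairpin_id: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"mature {self.mature_id!r}: invalid span {self.start}..{self.end} "
                "(1-based inclusive, start <= end required)"
            )
        if self.arm not in ("5p", "3p"):
            raise FormatError(f"mature {self.mature_id!r}: arm must be 5p or 3p")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReadRecord:
    """A single small-RNA read; quality is carried verbatim but never used."""

    id: str
    sequence: str
    quality: str | None = None


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    Sequences are upper-cased with T converted to U; record order is
    preserved. Duplicate ids and empty records are rejected.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: FASTA record with empty header")
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
            seq = normalize_sequence(str(rec.seq))
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            seen.add(rec.id)
            out.append((rec.id, seq))
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def read_hairpins(path: str | Path) -> dict[str, HairpinRecord]:
    """Read a hairpin reference FASTA, enforcing the strict ACGU alphabet."""
    return {name: HairpinRecord(name, seq) for name, seq in read_fasta(path)}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_mature_table(
    path: str | Path,
    hairpins: Mapping[str, HairpinRecord] | None = None,
) -> list[MatureAnnotation]:
    """Read the mature-arm annotation TSV.

    Expected columns: mature_id, hairpin_id, start, end, arm. When a hairpin
    reference is supplied, coordinates are validated against it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mature_id": str, "hairpin_id": str})
    required = ["mature_id", "hairpin_id", "start", "end", "arm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: mature table missing columns {missing}")
    annotations: list[MatureAnnotation] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        ann = MatureAnnotation(
            row.mature_id, row.hairpin_id, int(row.start), int(row.end), str(row.arm)
        )
        if ann.mature_id in seen:
            raise FormatError(f"{path}: duplicate mature_id {ann.mature_id!r}")
        seen.add(ann.mature_id)
        if hairpins is not None:
            if ann.hairpin_id not in hairpins:
                raise FormatError(
                    f"{path}: mature {ann.mature_id!r} references unknown hairpin "
                    f"{ann.hairpin_id!r}"
                )
            if ann.end > len(hairpins[ann.hairpin_id]):
                raise FormatError(
                    f"{path}: mature {ann.mature_id!r} span {ann.start}..{ann.end} "
                    f"exceeds hairpin length {len(hairpins[ann.hairpin_id])}"
                )
        annotations.append(ann)
    return annotations


def write_mature_table(annotations: Iterable[MatureAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (a.mature_id, a.hairpin_id, a.start, a.end, a.arm)
            for a in annotations
        ],
        columns=["mature_id", "hairpin_id", "start", "end", "arm"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a (possibly gzipped) FASTQ file into ReadRecords.

    Sequences are normalized as in :func:`read_fasta`; quality strings are
    retained verbatim. A sequence/quality length mismatch is a parse error.
    """
    out: list[ReadRecord] = []
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                out.append(ReadRecord(rec.id, normalize_sequence(str(rec.seq)), qual))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# Declared TSV schemas: name -> required leading columns. The matrix schema
# is wide (one column per sample) so only its index column is fixed.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "counts": ["sample_id", "mature_id", "position", "ref_base", "A", "C", "G", "U"],
    "sites": ["sample_id", "mature_id", "position", "ref", "alt", "k", "n", "level"],
    "matrix": ["site"],
    "differential": [
        "site",
        "mature_id",
        "position",
        "welch_t",
        "welch_df",
        "p_raw",
        "p_bh",
        "significant",
    ],
    "site_matches": ["isomir", "utr_id", "start", "site_type"],
    "pool_comparison": [
        "n_targets_a",
        "n_targets_b",
        "n_shared",
        "shared_fraction",
        "shared_of_a",
        "shared_of_b",
    ],
    "motif_counts": ["trinucleotide", "edited_count", "background_count"],
    "ground_truth_counts": ["sample_id", "mature_id", "total_reads"],
    "ground_truth_sites": [
        "sample_id",
        "mature_id",
        "position",
        "edited_reads",
        "total_reads",
        "group",
        "true_fraction",
    ],
    "design": ["sample_id", "group"],
    "residuals": ["sample_id", "edited", "total", "fitted", "residual"],
}


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a results table as TSV after validating it against a schema.

    Floats are rendered with full precision (17 significant digits) so a
    read-back reproduces values to well within 1e-9 relative.
    """
    if schema not in TABLE_SCHEMAS:
        raise FormatError(f"unknown table schema {schema!r}")
    for col in TABLE_SCHEMAS[schema]:
        if col not in df.columns:
            raise FormatError(f"schema {schema!r}: missing column {col!r}")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if schema is not None:
        for col in TABLE_SCHEMAS[schema]:
            if col not in df.columns:
                raise FormatError(f"{path}: schema {schema!r} missing column {col!r}")
    return df
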