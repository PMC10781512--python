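"""Seed-edit target-pool analysis.

A seed edit (an A->G change inside miRNA positions 2-8) rewrites the
canonical target-site vocabulary of the miRNA. This module derives the
edited and non-edited isomiR sequences, builds their canonical TargetScan
site patterns (8mer, 7mer-m8, 7mer-A1), scans a 3'UTR set for matches and
compares the resulting target pools.

Site-pattern conventions (UTR sequence, 5'->3'):

* 7mer-m8: perfect Watson-Crick match to seed positions 2-8;
* 8mer: the 7mer-m8 match followed by an A opposite miRNA position 1;
* 7mer-A1: match to positions 2-7 followed by that A.

The A opposite position 1 is a literal adenosine in the UTR regardless of
the miRNA's first base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._sequences import normalize_sequence, reverse_complement_rna

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}


@dataclass(frozen=True)
class IsomiR:
    """A mature miRNA sequence variant, optionally carrying one A->G edit."""

    mature_id: str
    sequence: str
    edit_position: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError("mature sequence must be at least 8 nt for a seed")

    @property
    def seed(self) -> str:
        return seed_of(self.sequence)

    @property
    def label(self) -> str:
        if self.edit_position is None:
            return f"{self.mature_id}"
        return f"{self.mature_id}(+{self.edit_position})"


@dataclass(frozen=True)
class SiteMatch:
    utr_id: str
    start: int  # 1-based on the UTR
    site_type: str


@dataclass(frozen=True)
class TargetPoolComparison:
    targets_a: frozenset[str]
    targets_b: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.targets_a & self.targets_b)

    @property
    def shared_fraction(self) -> float:
        """Jaccard overlap: shared / union (0 when both pools are empty)."""
        union = self.targets_a | self.targets_b
        if not union:
            return 0.0
        return self.n_shared / len(union)

    @property
    def shared_of_a(self) -> float:
        return self.n_shared / len(self.targets_a) if self.targets_a else 0.0

    @property
    def shared_of_b(self) -> float:
        return self.n_shared / len(self.targets_b) if self.targets_b else 0.0

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_targets_a": len(self.targets_a),
                    "n_targets_b": len(self.targets_b),
                    "n_shared": self.n_shared,
                    "shared_fraction": self.shared_fraction,
                    "shared_of_a": self.shared_of_a,
                    "shared_of_b": self.shared_of_b,
                }
            ]
        )


def apply_edit(sequence: str, position: int) -> str:
    """Apply an A->G edit at a 1-based position (inosine read as G)."""
    if not (1 <= position <= len(sequence)):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    if sequence[position - 1] != "A":
        raise ValueError(
            f"base at position {position} is {sequence[position - 1]!r}, not A"
        )
    return sequence[: position - 1] + "G" + sequence[position:]


def seed_of(sequence: str) -> str:
    """The seed region: miRNA positions 2-8 inclusive (7 nt)."""
    if len(sequence) < 8:
        raise ValueError("sequence shorter than 8 nt has no full seed")
    return sequence[1:8]


def site_patterns(seed: str) -> dict[str, str]:
    """Canonical UTR site strings for a 7-nt seed.

    Returns {'8mer': ..., '7mer-m8': ..., '7mer-A1': ...}.
    """
    if len(seed) != 7:
        raise ValueError("seed must be exactly 7 nt (miRNA positions 2-8)")
    bad = set(seed) - set("ACGU")
    if bad:
        raise ValueError(f"seed contains non-ACGU characters: {sorted(bad)}")
    m8 = reverse_complement_rna(seed)  # match to positions 2-8
    a1 = reverse_complement_rna(seed[:6]) + "A"  # positions 2-7 + literal A
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": a1}


def _find_all(text: str, pattern: str) -> Iterable[int]:
    """All (possibly overlapping) 0-based match starts of pattern in text."""
    start = text.find(pattern)
    while start != -1:
        yield start
        start = text.find(pattern, start + 1)


def scan_utr(utr_id: str, utr_sequence: str, patterns: Mapping[str, str]) -> list[SiteMatch]:
    """Find all canonical sites of one isomiR in one UTR.

    Overlapping classifications resolve by strength (8mer > 7mer-m8 >
    7mer-A1): a 7mer-m8 starting where an 8mer starts, or the 7mer-A1
    embedded in an 8mer, is not reported separately.
    """
    seq = normalize_sequence(utr_sequence)
    matches: list[SiteMatch] = []
    eightmer_starts = set(_find_all(seq, patterns["8mer"]))
    for s in sorted(eightmer_starts):
        matches.append(SiteMatch(utr_id, s + 1, "8mer"))
    for s in _find_all(seq, patterns["7mer-m8"]):
        if s not in eightmer_starts:
            matches.append(SiteMatch(utr_id, s + 1, "7mer-m8"))
    for s in _find_all(seq, patterns["7mer-A1"]):
        if (s - 1) not in eightmer_starts:
            matches.append(SiteMatch(utr_id, s + 1, "7mer-A1"))
    return sorted(matches, key=lambda m: (m.start, _SITE_RANK[m.site_type]))


def scan_utr_set(
    utrs: Sequence[tuple[str, str]], patterns: Mapping[str, str]
) -> list[SiteMatch]:
    out: list[SiteMatch] = []
    for utr_id, seq in utrs:
        out.extend(scan_utr(utr_id, seq, patterns))
    return out


def targets_of(matches: Iterable[SiteMatch]) -> frozenset[str]:
    """UTRs carrying at least one site of any accepted type."""
    return frozenset(m.utr_id for m in matches)


def compare_target_pools(
    matches_a: Iterable[SiteMatch], matches_b: Iterable[SiteMatch]
) -> TargetPoolComparison:
    return TargetPoolComparison(targets_of(matches_a), targets_of(matches_b))


def locate_edits(reference_sequence: str, variant_sequence: str) -> list[int]:
    """1-based positions where the reference has A and the variant has G.

    Any other difference between the two sequences is an error: the variant
    must be obtainable from the reference by A->G edits alone.
    """
    ref = normalize_sequence(reference_sequence)
    var = normalize_sequence(variant_sequence)
    if len(ref) != len(var):
        raise ValueError("sequences differ in length; not an editing variant")
    positions = []
    for i, (a, b) in enumerate(zip(ref, var), start=1):
        if a == b:
            continue
        if a == "A" and b == "G":
            positions.append(i)
        else:
            raise ValueError(f"non-A->G difference at position {i}: {a}->{b}")
    return positions


def target_switch_analysis(
    mature_id: str,
    mature_sequence: str,
    edit_position: int,
    utrs: Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, TargetPoolComparison]:
    """Full edited-vs-non-edited target comparison over a UTR set.

    Returns the combined site-match table (``site_matches`` schema, with an
    ``isomir`` column distinguishing the two forms; pool A = non-edited,
    pool B = edited) and the pool comparison.
    """
    seq = normalize_sequence(mature_sequence)
    non_edited = IsomiR(mature_id, seq)
    edited = IsomiR(mature_id, apply_edit(seq, edit_position), edit_position)
    rows = []
    pools = {}
    for iso in (non_edited, edited):
        matches = scan_utr_set(utrs, site_patterns(iso.seed))
        pools[iso.label] = matches
        rows.extend(
            {"isomir": iso.label, "utr_id": m.utr_id, "start": m.start,
             "site_type": m.site_type}
            for m in matches
        )
    table = pd.DataFrame(rows, columns=["isomir", "utr_id", "start", "site_type"])
    comparison = compare_target_pools(pools[non_edited.label], pools[edited.label])
    return table, comparison
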