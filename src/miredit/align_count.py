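"""Adapter trimming, bounded-mismatch alignment to hairpins, and tallies.

Reads are aligned ungapped, sense-strand only, against every hairpin; the
best placement is the one with fewest mismatches (ties across distinct
hairpins are ambiguous and discarded, ties within one hairpin resolve to
the smallest offset). Mismatch positions are tallied as observed — they are
the editing signal. Ambiguity codes (N) never match and are never tallied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HairpinRecord, MatureAnnotation, ReadRecord

MIN_READ_LENGTH = 15


@dataclass(frozen=True)
class AlignmentParams:
    max_mismatch: int = 2
    adapter: str | None = None
    min_overlap_adapter: int = 6
    mature_5p_tolerance: int = 2

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.min_overlap_adapter < 0:
            raise ValueError("alignment parameters must be non-negative")
        if self.mature_5p_tolerance < 0:
            raise ValueError("mature_5p_tolerance must be non-negative")


@dataclass(frozen=True)
class Alignment:
    """A unique best placement: 1-based offset of the read on the hairpin."""

    hairpin_id: str
    offset: int
    n_mismatch: int


#: sentinel outcomes for reads without a usable unique placement
UNALIGNED = "unaligned"
AMBIGUOUS = "ambiguous"
TOO_SHORT = "too_short"


def trim_adapter(sequence: str, params: AlignmentParams) -> str:
    """Remove the longest read suffix exactly matching an adapter prefix.

    Only overlaps of at least ``min_overlap_adapter`` nucleotides count;
    reads without a qualifying overlap are returned unchanged.
    """
    adapter = params.adapter
    if not adapter:
        return sequence
    max_ov = min(len(sequence), len(adapter))
    for ov in range(max_ov, params.min_overlap_adapter - 1, -1):
        if sequence.endswith(adapter[:ov]):
            return sequence[: len(sequence) - ov]
    return sequence


class HairpinIndex:
    """Byte-encoded hairpins supporting fast sliding-window mismatch counts."""

    def __init__(self, hairpins: Mapping[str, HairpinRecord]):
        self.ids = list(hairpins)
        self.arrays = {
            hid: np.frombuffer(hairpins[hid].sequence.encode(), dtype=np.uint8)
            for hid in self.ids
        }

    def placements(self, read: str) -> Iterable[tuple[str, int, int]]:
        """Yield (hairpin_id, offset_1based, n_mismatch) for every placement."""
        r = np.frombuffer(read.encode(), dtype=np.uint8)
        m = len(r)
        for hid in self.ids:
            h = self.arrays[hid]
            if len(h) < m:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(h, m)
            mismatches = (windows != r).sum(axis=1)
            for off0 in range(mismatches.shape[0]):
                yield hid, off0 + 1, int(mismatches[off0])


def align_read(
    read: str | ReadRecord,
    hairpins: Mapping[str, HairpinRecord] | HairpinIndex,
    params: AlignmentParams = AlignmentParams(),
) -> Alignment | str:
    """Align one (already trimmed) read; returns an Alignment or a sentinel.

    N (or any non-ACGU character) in the read never matches any reference
    base, so it contributes a mismatch at every placement.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if len(seq) < MIN_READ_LENGTH:
        return TOO_SHORT
    index = hairpins if isinstance(hairpins, HairpinIndex) else HairpinIndex(hairpins)

    best_mm = params.max_mismatch + 1
    best: tuple[str, int] | None = None
    tied_other_hairpin = False
    for hid, offset, mm in index.placements(seq):
        if mm < best_mm:
            best_mm, best, tied_other_hairpin = mm, (hid, offset), False
        elif mm == best_mm and best is not None:
            if hid != best[0]:
                tied_other_hairpin = True
            # equal score within the same hairpin: keep the smaller offset
    if best is None or best_mm > params.max_mismatch:
        return UNALIGNED
    if tied_other_hairpin:
        return AMBIGUOUS
    return Alignment(best[0], best[1], best_mm)


def assign_mature(
    alignment: Alignment,
    annotations: Sequence[MatureAnnotation],
    read_length: int,
    params: AlignmentParams = AlignmentParams(),
) -> MatureAnnotation | None:
    """Assign an aligned read to a mature arm, or None.

    The read start must fall within ``mature_5p_tolerance`` of the annotated
    mature start and the mature span must cover at least 90% of the read;
    reads landing in the loop or deep in the star arm return None.
    """
    read_start = alignment.offset
    read_end = alignment.offset + read_length - 1
    for ann in annotations:
        if ann.hairpin_id != alignment.hairpin_id:
            continue
        if abs(read_start - ann.start) > params.mature_5p_tolerance:
            continue
        overlap = min(read_end, ann.end) - max(read_start, ann.start) + 1
        if overlap >= 0.9 * read_length:
            return ann
    return None


def tally_positions(
    assigned: Iterable[tuple[str, str, Alignment, MatureAnnotation]],
    hairpins: Mapping[str, HairpinRecord],
) -> pd.DataFrame:
    """Accumulate per-position base counts in mature coordinates.

    ``assigned`` yields (sample_id, read_sequence, alignment, annotation).
    Positions outside the mature span are ignored; non-ACGU read characters
    are not counted. Returns a table in the ``counts`` schema, one row per
    (sample, mature, position) with the reference base and A/C/G/U tallies.
    """
    tallies: dict[tuple[str, str, int], list[int]] = {}
    base_idx = {"A": 0, "C": 1, "G": 2, "U": 3}
    spans: dict[str, tuple[int, int, str]] = {}
    for sample_id, seq, aln, ann in assigned:
        if ann.mature_id not in spans:
            hp = hairpins[ann.hairpin_id].sequence
            spans[ann.mature_id] = (ann.start, ann.end, hp[ann.start - 1 : ann.end])
        start, end, _ = spans[ann.mature_id]
        for j, base in enumerate(seq):
            hp_pos = aln.offset + j  # 1-based hairpin coordinate
            mat_pos = hp_pos - start + 1
            if mat_pos < 1 or hp_pos > end:
                continue
            b = base_idx.get(base)
            if b is None:
                continue
            key = (sample_id, ann.mature_id, mat_pos)
            if key not in tallies:
                tallies[key] = [0, 0, 0, 0]
            tallies[key][b] += 1

    rows = []
    for (sample_id, mature_id, pos), counts in sorted(tallies.items()):
        ref_base = spans[mature_id][2][pos - 1]
        rows.append((sample_id, mature_id, pos, ref_base, *counts))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "mature_id", "position", "ref_base", "A", "C", "G", "U"],
    )


def align_and_count(
    reads_by_sample: Mapping[str, Sequence[ReadRecord]],
    hairpins: Mapping[str, HairpinRecord],
    annotations: Sequence[MatureAnnotation],
    params: AlignmentParams = AlignmentParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trim, align and tally every sample's reads.

    Identical read sequences share one alignment (small-RNA libraries are
    dominated by duplicate reads, so placements are memoized). Returns the
    counts table and a per-sample summary of read fates.
    """
    index = HairpinIndex(hairpins)
    cache: dict[str, tuple] = {}
    assigned = []
    summary_rows = []
    for sample_id, reads in reads_by_sample.items():
        fates = {"assigned": 0, UNALIGNED: 0, AMBIGUOUS: 0, TOO_SHORT: 0, "no_mature": 0}
        for read in reads:
            seq = trim_adapter(read.sequence, params)
            hit = cache.get(seq)
            if hit is None:
                aln = align_read(seq, index, params)
                if isinstance(aln, Alignment):
                    ann = assign_mature(aln, annotations, len(seq), params)
                    hit = (aln, ann)
                else:
                    hit = (aln, None)
                cache[seq] = hit
            aln, ann = hit
            if not isinstance(aln, Alignment):
                fates[aln] += 1
            elif ann is None:
                fates["no_mature"] += 1
            else:
                fates["assigned"] += 1
                assigned.append((sample_id, seq, aln, ann))
        summary_rows.append((sample_id, *fates.values()))
    counts = tally_positions(assigned, hairpins)
    summary = pd.DataFrame(
        summary_rows,
        columns=["sample_id", "assigned", "unaligned", "ambiguous", "too_short",
                 "no_mature"],
    )
    return counts, summary
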