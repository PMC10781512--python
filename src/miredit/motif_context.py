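"""Trinucleotide context of edited adenosines vs the adenosine background.

ADAR enzymes prefer particular sequence neighbourhoods; in mature miRNAs
the dominant substrate context is 5'-UAG-3'. This module tabulates the
X-A-Z context (using the UNEDITED reference base at the centre: the motif
question concerns the ADAR substrate, not the product read as G) of called
editing sites, against the background of every adenosine in the expressed
mature miRNAs. An optional per-motif Fisher exact enrichment is available;
the plain count table is the default output.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .io_formats import HairpinRecord, MatureAnnotation


def site_context(
    mature_sequence: str,
    position: int,
    hairpin_sequence: str | None = None,
    mature_start: int | None = None,
) -> str:
    """Trinucleotide context (5' base, A, 3' base) of an edited adenosine.

    ``position`` is 1-based on the mature sequence, whose base there must
    be A (the unedited reference). At mature boundaries the flanking
    hairpin base is used when the hairpin and the mature start coordinate
    are supplied; otherwise the missing side is padded with '-'.
    """
    if not (1 <= position <= len(mature_sequence)):
        raise ValueError(f"position {position} outside the mature sequence")
    if mature_sequence[position - 1] != "A":
        raise ValueError(
            f"centre base at position {position} is "
            f"{mature_sequence[position - 1]!r}, not A"
        )

    def flank(mature_offset: int) -> str:
        if 0 <= mature_offset < len(mature_sequence):
            return mature_sequence[mature_offset]
        if hairpin_sequence is not None and mature_start is not None:
            hp_pos = mature_start - 1 + mature_offset  # 0-based hairpin index
            if 0 <= hp_pos < len(hairpin_sequence):
                return hairpin_sequence[hp_pos]
        return "-"

    return flank(position - 2) + "A" + flank(position)


def motif_table(
    sites: pd.DataFrame,
    hairpins: Mapping[str, HairpinRecord],
    annotations: Sequence[MatureAnnotation],
    expressed_matures: Sequence[str] | None = None,
    with_enrichment: bool = False,
) -> pd.DataFrame:
    """Count trinucleotide contexts of edited sites and background adenosines.

    ``sites`` is a sites-schema table (only unique (mature_id, position)
    pairs are counted — the motif is a property of the site, not of the
    per-sample measurements). The background is every adenosine in the
    expressed mature sequences (default: all annotated matures), with
    hairpin-padded boundary contexts. With ``with_enrichment`` a two-sided
    Fisher exact test per motif (edited vs background composition) and BH
    adjustment are appended.

    Returns a ``motif_counts``-schema table sorted by edited count.
    """
    ann_by_mature = {a.mature_id: a for a in annotations}
    if expressed_matures is None:
        expressed_matures = list(ann_by_mature)

    def mature_seq(mature_id: str) -> tuple[str, str, int]:
        ann = ann_by_mature[mature_id]
        hp = hairpins[ann.hairpin_id].sequence
        return hp[ann.start - 1 : ann.end], hp, ann.start

    edited_counts: dict[str, int] = {}
    if len(sites):
        unique_sites = sites[["mature_id", "position"]].drop_duplicates()
        for mature_id, position in unique_sites.itertuples(index=False):
            if mature_id not in ann_by_mature:
                raise ValueError(f"site on unannotated mature {mature_id!r}")
            mat, hp, start = mature_seq(mature_id)
            tri = site_context(mat, int(position), hp, start)
            edited_counts[tri] = edited_counts.get(tri, 0) + 1

    background_counts: dict[str, int] = {}
    for mature_id in expressed_matures:
        mat, hp, start = mature_seq(mature_id)
        for pos in range(1, len(mat) + 1):
            if mat[pos - 1] == "A":
                tri = site_context(mat, pos, hp, start)
                background_counts[tri] = background_counts.get(tri, 0) + 1

    motifs = sorted(set(edited_counts) | set(background_counts))
    out = pd.DataFrame(
        {
            "trinucleotide": motifs,
            "edited_count": [edited_counts.get(m, 0) for m in motifs],
            "background_count": [background_counts.get(m, 0) for m in motifs],
        }
    )
    out = out.sort_values(
        ["edited_count", "background_count"], ascending=False, ignore_index=True
    )
    if with_enrichment and len(out):
        total_e = out["edited_count"].sum()
        total_b = out["background_count"].sum()
        pvals = []
        for _, row in out.iterrows():
            table = [
                [row["edited_count"], total_e - row["edited_count"]],
                [row["background_count"], total_b - row["background_count"]],
            ]
            pvals.append(stats.fisher_exact(table, alternative="two-sided")[1])
        out["fisher_p"] = pvals
        out["fisher_p_bh"] = bh_adjust(out["fisher_p"])
    return out
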