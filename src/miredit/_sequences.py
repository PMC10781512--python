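"""Small sequence utilities and the miR-376a-3p reference constants.

Everything internal works on the RNA alphabet (A/C/G/U), 5'->3'.
"""

from __future__ import annotations

RNA_BASES = ("A", "C", "G", "U")

_DNA_TO_RNA = str.maketrans("Tt", "Uu")
_RNA_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")
_RNA_TO_DNA_COMPLEMENT = str.maketrans("ACGUacgu", "TGCAtgca")


def normalize_sequence(seq: str) -> str:
    """Upper-case and convert DNA T to RNA U. Idempotent."""
    return seq.upper().translate(_DNA_TO_RNA)


def reverse_complement_rna(seq: str) -> str:
    """Reverse complement within the RNA alphabet (A<->U, C<->G)."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def reverse_complement_to_dna(seq: str) -> str:
    """Reverse complement of an RNA sequence written in the DNA alphabet.

    This is the sequence of a DNA antisense oligonucleotide (antimir)
    complementary to the given RNA stretch.
    """
    return seq.translate(_RNA_TO_DNA_COMPLEMENT)[::-1]


# Mature miR-376a-3p, the heavily seed-edited brain miRNA. The edited form
# carries G at mature position +6 (inosine read as guanosine); the unedited
# form carries the genomic A. The antimirs are DNA antisense oligos
# complementary to mature positions 2-16 of each isomiR.
MIR376A_3P_EDITED = "AUCAUGGAGGAAAAUCCACGU"
MIR376A_3P_UNEDITED = "AUCAUAGAGGAAAAUCCACGU"
MIR376A_3P_EDIT_POSITION = 6
ANTA_E_DNA = "GATTTTCCTCCATGA"  # antimir against the edited form
ANTA_N_DNA = "GATTTTCCTCTATGA"  # antimir against the unedited form
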