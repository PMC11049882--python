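"""Genetic-code metadata shared by the codon-usage modules.

Everything here is derived from the standard genetic code (NCBI table 1,
which agrees with the bacterial/plastid table 11 on all sense-codon
degeneracies). Met (ATG) and Trp (TGG) have no synonymous partner and are
excluded from bias statistics; stop codons are tracked separately.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_BASES = "TCAG"

STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

STOP_CODONS: frozenset[str] = frozenset(STANDARD_TABLE.stop_codons)

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(STANDARD_TABLE.forward_table)

SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acid -> tuple of synonymous codons (all 20 amino acids)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, ())
AA_TO_CODONS = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AA_TO_CODONS
}

#: amino acid -> family degeneracy (number of synonymous codons)
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: the 59 informative codons: sense codons minus ATG (Met) and TGG (Trp)
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)

#: amino acids with >1 synonymous codon (18 families)
SYNONYMOUS_AAS: tuple[str, ...] = tuple(
    aa for aa in sorted(AA_TO_CODONS) if DEGENERACY[aa] > 1
)

#: four-fold degenerate families (third position fully free): Val Pro Thr Ala Gly
FOURFOLD_AAS: tuple[str, ...] = tuple(aa for aa in SYNONYMOUS_AAS if DEGENERACY[aa] == 4)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


assert len(INFORMATIVE_CODONS) == 59
assert len(SYNONYMOUS_AAS) == 18
assert set(DEGENERACY[a] for a in SYNONYMOUS_AAS) == {2, 3, 4, 6}
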