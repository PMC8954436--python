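"""Genetic-code tables and small sequence helpers shared across modules.

All sequences are handled internally as DNA over {A,C,G,T,N}; codon labels
are converted to the RNA alphabet (UAA, not TAA) only at the reporting
layer, via :func:`to_rna`.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

#: The three termination codons of translation table 11 (bacterial,
#: archaeal and plant plastid code), DNA alphabet.
DNA_STOPS: tuple[str, ...] = ("TAA", "TAG", "TGA")
RNA_STOPS: tuple[str, ...] = ("UAA", "UAG", "UGA")

BASES: tuple[str, ...] = ("A", "C", "G", "T")

ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=3))

_RNA_TRANS = str.maketrans("Tt", "Uu")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Fold every letter that is not an unambiguous base to N.  Covers the
# remaining IUPAC ambiguity codes plus anything unexpected.
_IUPAC_FOLD = str.maketrans(
    {c: "N" for c in "BDEFHIJKLMOPQRSUVWXYZ"}
)


def to_rna(codon_or_seq: str) -> str:
    """Render a DNA string in the RNA alphabet (T -> U)."""
    return codon_or_seq.translate(_RNA_TRANS)


def to_dna(codon_or_seq: str) -> str:
    return codon_or_seq.replace("U", "T").replace("u", "t")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_sequence(raw: str) -> str:
    """Uppercase and fold non-ACGT IUPAC letters to N."""
    return raw.upper().translate(_IUPAC_FOLD)


@lru_cache(maxsize=None)
def stop_codons(genetic_code_id: int = 11) -> tuple[str, ...]:
    """DNA stop codons of an NCBI translation table."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    return tuple(table.stop_codons)


@lru_cache(maxsize=None)
def sense_codons(genetic_code_id: int = 11) -> tuple[str, ...]:
    """The sense (non-stop) codons of a translation table, sorted."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    return tuple(sorted(table.forward_table))


@lru_cache(maxsize=None)
def synonymous_families(genetic_code_id: int = 11) -> dict[str, tuple[str, ...]]:
    """Map amino acid -> tuple of codons encoding it (stops excluded)."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(codons) for aa, codons in fams.items()}


@lru_cache(maxsize=None)
def codon_family(genetic_code_id: int = 11) -> dict[str, tuple[str, ...]]:
    """Map each sense codon to the tuple of its synonymous family members."""
    out: dict[str, tuple[str, ...]] = {}
    for codons in synonymous_families(genetic_code_id).values():
        for c in codons:
            out[c] = codons
    return out


def iter_codons(cds: str):
    """Yield successive in-frame triplets of a CDS (trailing partials dropped)."""
    for i in range(0, len(cds) - len(cds) % 3, 3):
        yield cds[i : i + 3]
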