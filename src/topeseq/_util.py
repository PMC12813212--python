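"""Shared sequence helpers built on the standard genetic code."""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

_STD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: amino acid -> tuple of synonymous codons (standard code, no stops)
SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in _STD_TABLE.forward_table.items():
    SYNONYMOUS_CODONS.setdefault(aa, [])
    SYNONYMOUS_CODONS[aa].append(codon)
SYNONYMOUS_CODONS = {aa: tuple(sorted(cs)) for aa, cs in SYNONYMOUS_CODONS.items()}

STOP_CODONS = frozenset(_STD_TABLE.stop_codons)


def translate(dna: str) -> str:
    """Translate a coding DNA string under the standard genetic code."""
    return str(Seq(dna).translate())


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept an integer seed or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def encode_peptides(peptides, length: int | None = None) -> np.ndarray:
    """Encode equal-length peptides as an (n, k) int8 matrix over AA_ALPHABET."""
    peptides = list(peptides)
    if not peptides:
        return np.zeros((0, 0 if length is None else length), dtype=np.int8)
    k = len(peptides[0])
    out = np.empty((len(peptides), k), dtype=np.int8)
    for i, p in enumerate(peptides):
        if len(p) != k:
            raise ValueError("peptides must be of equal length")
        try:
            out[i] = [AA_INDEX[a] for a in p]
        except KeyError as e:
            raise ValueError(f"non-standard residue {e} in peptide {p!r}") from None
    return out
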