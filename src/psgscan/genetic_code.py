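"""Universal genetic code, sense-codon state space, and IUPAC nucleotide codes.

The codon substitution machinery works on the 61 sense codons of the
universal code (stop codons TAA, TAG, TGA are excluded from the state
space).  Codons are indexed in lexicographic order of their nucleotides
with the alphabet order A, C, G, T.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: the 61 sense codons, lexicographic in A<C<G<T order
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
N_STATES = len(SENSE_CODONS)  # 61

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = tuple(_CODON_TABLE[c] for c in SENSE_CODONS)

#: codon index -> (i, j, k) nucleotide indices at the three positions
CODON_NT = np.array([[NT_INDEX[nt] for nt in c] for c in SENSE_CODONS], dtype=np.int8)

# Two-base IUPAC ambiguity codes (unordered base pairs) and their inverses.
IUPAC_2 = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
IUPAC_BASES = {code: pair for pair, code in IUPAC_2.items()}
AMBIGUITY_CODES = frozenset(IUPAC_BASES)
#: every symbol a consensus sequence may contain
ALLOWED_SYMBOLS = frozenset("ACGTN-") | AMBIGUITY_CODES | frozenset("BDHV")


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) for an unambiguous codon."""
    return _CODON_TABLE[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def _pair_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks: single-nucleotide change, transition, synonymous."""
    diff = (CODON_NT[:, None, :] != CODON_NT[None, :, :])
    single = diff.sum(axis=2) == 1
    pos = np.argmax(diff, axis=2)
    a = np.take_along_axis(CODON_NT[:, None, :].repeat(N_STATES, 1), pos[..., None], 2)[..., 0]
    b = np.take_along_axis(CODON_NT[None, :, :].repeat(N_STATES, 0), pos[..., None], 2)[..., 0]
    # transitions: A<->G (0,2), C<->T (1,3)
    ts = ((a + b) % 4 == 2) & (a != b)
    aa_idx = np.array([ord(x) for x in CODON_AA])
    syn = aa_idx[:, None] == aa_idx[None, :]
    return single, ts & single, syn


SINGLE_STEP, TRANSITION, SYNONYMOUS = _pair_masks()
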