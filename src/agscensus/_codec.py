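"""Shared sequence encodings: amino-acid / nucleotide integer codes, the codon
table used for six-frame translation, and the scoring matrix.

All alignment code in the package operates on small integer codes so that the
numba kernels and the vectorized batch paths see identical inputs.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

# Amino-acid alphabet in BLOSUM62 order.  X (code 22) doubles as the code for
# every unknown/ambiguous residue; '*' (code 23) is a stop codon.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_X = AA_ALPHABET.index("X")
AA_STOP = AA_ALPHABET.index("*")
N_AA = len(AA_ALPHABET)

# Nucleotide codes: A C G T = 0..3, everything else (incl. N) = 4.
DNA_ALPHABET = "ACGTN"
DNA_N = 4

_AA_LUT = np.full(256, AA_X, dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_LUT[ord(_c)] = _i
    _AA_LUT[ord(_c.lower())] = _i

_DNA_LUT = np.full(256, DNA_N, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _DNA_LUT[ord(_c)] = _i
    _DNA_LUT[ord(_c.lower())] = _i


def encode_aa(seq: str) -> np.ndarray:
    """Encode a protein string to int8 codes (unknown letters become X)."""
    return _AA_LUT[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]


def decode_aa(codes: np.ndarray) -> str:
    return "".join(AA_ALPHABET[c] for c in codes)


def encode_dna(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes; any non-ACGT letter becomes N."""
    return _DNA_LUT[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]


def decode_dna(codes: np.ndarray) -> str:
    return "".join(DNA_ALPHABET[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on integer codes (N maps to N)."""
    comp = np.where(codes < 4, 3 - codes, DNA_N).astype(np.int8)
    return comp[::-1]


@lru_cache(maxsize=1)
def codon_table() -> np.ndarray:
    """Codon code -> amino-acid code, index = b0*25 + b1*5 + b2 over base-5
    nucleotide codes.  Any codon containing an ambiguous base translates to X;
    stop codons translate to '*'.
    """
    table = np.full(125, AA_X, dtype=np.int8)
    bases = "ACGT"
    for i, b0 in enumerate(bases):
        for j, b1 in enumerate(bases):
            for k, b2 in enumerate(bases):
                aa = str(Seq(b0 + b1 + b2).translate())
                table[i * 25 + j * 5 + k] = _AA_LUT[ord(aa)]
    return table


# Inverse table for reverse translation: aa code -> list of codon strings.
@lru_cache(maxsize=1)
def codons_by_aa() -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    bases = "ACGT"
    for b0 in bases:
        for b1 in bases:
            for b2 in bases:
                codon = b0 + b1 + b2
                aa = str(Seq(codon).translate())
                code = int(_AA_LUT[ord(aa)])
                out.setdefault(code, []).append(codon)
    return out


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Scoring matrix over AA_ALPHABET as int32, with every stop-codon score
    forced to the matrix minimum (alignments may span stops but never profit
    from them).
    """
    m = substitution_matrices.load(name)
    mat = np.zeros((N_AA, N_AA), dtype=np.int32)
    alpha = m.alphabet
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            aa = a if a in alpha else "X"
            bb = b if b in alpha else "X"
            mat[i, j] = int(m[aa, bb])
    floor = int(mat.min())
    mat[AA_STOP, :] = floor
    mat[:, AA_STOP] = floor
    return mat
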