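"""Substitution matrices, codon translation and the elementary codon score.

The aligner scores a nucleotide triplet against an amino acid by translating
the triplet under the standard genetic code and looking the pair up in a
protein substitution matrix (BLOSUM62 by default).  Frame-shifted matches are
composites built on top of this elementary score, so everything downstream is
expressed in the same half-bit units as the matrix.

Scores are carried as floats throughout the package because the
homopolymer-reduced frame-shift penalties are non-integral fractions of the
gap costs.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "STOP",
    "STOP_SCORE",
    "NT_ALPHABET",
    "NT_CODE",
    "AA_ALPHABET",
    "AA_INDEX",
    "SubstitutionMatrix",
    "load_matrix",
    "translate_codon",
    "m3_score",
    "triplet_score_table",
]

#: Sentinel used for stop codons.
STOP = "*"

#: Score assigned to any triplet that translates to a stop codon, regardless
#: of the amino acid it faces.  Strictly worse than every BLOSUM entry so the
#: optimum never runs through a stop, while keeping the DP total order
#: well defined.
STOP_SCORE = -16.0

#: Nucleotide alphabet in flow-cycle order; ``N`` is the unknown base.
NT_ALPHABET = "TACG"
NT_CODE = {c: i for i, c in enumerate(NT_ALPHABET)}
NT_CODE["N"] = 4

#: Protein alphabet used internally: the 20 standard residues plus X.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

_STANDARD_TABLE = _BioCodonTable.unambiguous_dna_by_id[1]

#: triplet (T/A/C/G) -> amino acid or ``*``; exactly 64 entries.
CODON_TABLE: dict[str, str] = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    CODON_TABLE[_codon] = _aa
for _codon in _STANDARD_TABLE.stop_codons:
    CODON_TABLE[_codon] = STOP
assert len(CODON_TABLE) == 64


class SubstitutionMatrix:
    """A symmetric amino-acid substitution matrix in half-bit units.

    Wraps a Biopython :class:`~Bio.Align.substitution_matrices.Array` and
    guarantees that lookups of any pair drawn from the 20 standard residues,
    ``X`` and the stop sentinel never fail.
    """

    def __init__(self, name: str, array):
        self.name = name
        self._array = array
        alpha = set(array.alphabet)
        missing = [a for a in AA_ALPHABET if a not in alpha and a != "X"]
        if missing:
            raise ValueError(f"matrix {name!r} lacks residues {missing}")
        self._has_x = "X" in alpha
        # symmetry check over the declared alphabet
        mat = np.asarray(array)
        if mat.shape[0] != mat.shape[1] or not np.array_equal(mat, mat.T):
            raise ValueError(f"matrix {name!r} is not symmetric")

    def score(self, a: str, b: str) -> float:
        """Score of aligning residue *a* against residue *b*."""
        if a == STOP or b == STOP:
            return STOP_SCORE
        a = a if a in self._array.alphabet else "X"
        b = b if b in self._array.alphabet else "X"
        if not self._has_x and ("X" in (a, b)):
            return 0.0
        return float(self._array[a, b])

    def __repr__(self) -> str:  # pragma: no cover
        return f"SubstitutionMatrix({self.name!r})"


@lru_cache(maxsize=None)
def load_matrix(name_or_path: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a substitution matrix by name (e.g. ``"BLOSUM62"``) or from an
    NCBI-format whitespace-separated matrix text file."""
    if name_or_path.upper() in substitution_matrices.load():
        arr = substitution_matrices.load(name_or_path.upper())
        return SubstitutionMatrix(name_or_path.upper(), arr)
    arr = substitution_matrices.read(name_or_path)
    return SubstitutionMatrix(name_or_path, arr)


def translate_codon(triplet: str) -> str:
    """Translate a 3-nucleotide string under the standard genetic code.

    Any triplet containing ``N`` translates to the unknown residue ``X``.
    Stop codons return the ``*`` sentinel.
    """
    if len(triplet) != 3:
        raise ValueError(f"triplet must have length 3, got {triplet!r}")
    triplet = triplet.upper()
    if "N" in triplet:
        for c in triplet:
            if c not in NT_CODE:
                raise ValueError(f"non-nucleotide character {c!r} in triplet")
        return "X"
    try:
        return CODON_TABLE[triplet]
    except KeyError:
        raise ValueError(f"non-nucleotide character in triplet {triplet!r}") from None


def m3_score(aa: str, triplet: str, matrix: SubstitutionMatrix) -> float:
    """Elementary score of an amino acid versus a nucleotide triplet.

    The triplet is translated; stop-translating triplets score the fixed
    stop penalty.  Synonymous codons therefore always score identically.
    """
    t = translate_codon(triplet)
    if t == STOP:
        return STOP_SCORE
    return matrix.score(aa, t)


@lru_cache(maxsize=None)
def triplet_score_table(matrix_name: str = "BLOSUM62") -> np.ndarray:
    """Dense (125, 21) table of ``m3_score`` for every base-5 coded triplet
    (codes 0..3 = TACG, 4 = N) against every residue of :data:`AA_ALPHABET`.

    Used to vectorise query-profile construction; entries agree exactly with
    :func:`m3_score`.
    """
    matrix = load_matrix(matrix_name)
    table = np.empty((125, len(AA_ALPHABET)), dtype=np.float64)
    letters = NT_ALPHABET + "N"
    for a in range(5):
        for b in range(5):
            for c in range(5):
                trip = letters[a] + letters[b] + letters[c]
                code = 25 * a + 5 * b + c
                for ai, aa in enumerate(AA_ALPHABET):
                    table[code, ai] = m3_score(aa, trip, matrix)
    return table


def encode_nt(sequence: str) -> np.ndarray:
    """Encode a nucleotide string to int codes (TACG -> 0..3, N -> 4)."""
    try:
        return np.array([NT_CODE[c] for c in sequence], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-nucleotide character {e.args[0]!r}") from None


def encode_protein(sequence: str) -> np.ndarray:
    """Encode a protein string to indices into :data:`AA_ALPHABET`.

    Ambiguity codes (B, Z, J, U, O) map to X; stop characters are rejected.
    """
    out = np.empty(len(sequence), dtype=np.int64)
    for i, c in enumerate(sequence):
        if c == STOP:
            raise ValueError("stop character in protein sequence")
        out[i] = AA_INDEX.get(c, AA_INDEX["X"] if c in "BZJUOX" else -1)
        if out[i] < 0:
            raise ValueError(f"invalid protein residue {c!r}")
    return out
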