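"""FASTA input, alphabet normalization, 2-bit k-mer packing, reverse complement.

DNA words over {A,C,G,T} are packed at 2 bits per letter (a compression
rate of 4 versus 1 byte per letter), so a word of up to 32 letters fits in
a single 64-bit integer.  The letter code is chosen order-preserving
(A=00 < C=01 < G=10 < T=11, first letter in the most significant
position) so that sorting packed codes is identical to sorting the words
lexicographically — the property the dictionary stage relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

#: letters a packed k-mer may contain, in code order
ALPHABET = "ACGT"

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_LETTER = dict((v, k) for k, v in _CODE.items())

# translation table: keep ACGT (and their lowercase as uppercase), map every
# other IUPAC/unknown letter to N
_NORMALIZE = {}
for _c in range(256):
    ch = chr(_c).upper()
    _NORMALIZE[_c] = ch if ch in "ACGTN" else "N"
for _c in "acgtn":
    _NORMALIZE[ord(_c)] = _c.upper()
_NORMALIZE = str.maketrans(_NORMALIZE)

_SOFTMASK = str.maketrans({c: "N" for c in "acgtn"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for FASTA files that violate the expected single-record layout."""


class EncodingError(ValueError):
    """Raised when a word contains letters outside {A,C,G,T}."""


@dataclass
class Sequence:
    """A DNA sequence over the normalized alphabet {A,C,G,T,N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(f"unnormalized letters in sequence: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize(residues: str, respect_softmask: bool = False) -> str:
    """Fold a raw residue string onto {A,C,G,T,N}.

    Lowercase (soft-masked) letters are uppercased unless
    ``respect_softmask`` is set, in which case they become N and are thus
    invisible to the dictionary builder.  IUPAC ambiguity codes and any
    other character become N.
    """
    if respect_softmask:
        residues = residues.translate(_SOFTMASK)
    return residues.translate(_NORMALIZE)


def read_fasta(path: str | Path, respect_softmask: bool = False) -> Sequence:
    """Read the first record of a FASTA file as a normalized :class:`Sequence`.

    The pipeline is strictly pairwise, one sequence per side, so only the
    first record is used; additional records trigger a warning and are
    ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FastaFormatError(f"{path}: not a FASTA file (no '>' header)")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no sequence records")
    if len(records) > 1:
        log.warning(
            "%s: %d records found; using the first (%s) and ignoring the rest",
            path, len(records), records[0].id,
        )
    rec = records[0]
    residues = normalize(str(rec.seq), respect_softmask=respect_softmask)
    if not residues:
        raise FastaFormatError(f"{path}: record {rec.id} has an empty body")
    return Sequence(id=rec.id, residues=residues)


def write_fasta(seq: Sequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n")
        for i in range(0, len(seq.residues), width):
            fh.write(seq.residues[i : i + width] + "\n")


def encode_kmer(word: str) -> int:
    """Pack a word over {A,C,G,T} into an integer at 2 bits per letter.

    The packing is order-preserving: for equal-length words
    ``u < v`` lexicographically iff ``encode_kmer(u) < encode_kmer(v)``.
    """
    if len(word) > 32:
        raise EncodingError(f"word length {len(word)} exceeds 32")
    code = 0
    try:
        for ch in word:
            code = (code << 2) | _CODE[ch]
    except KeyError as exc:
        raise EncodingError(f"non-ACGT letter {exc.args[0]!r} in word") from None
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer` for a word of known length ``k``."""
    letters = []
    for shift in range(2 * (k - 1), -2, -2):
        letters.append(_LETTER[(code >> shift) & 3])
    return "".join(letters)


def encode_windows(residues: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes for every clean k-window of ``residues``.

    Returns ``(codes, positions)``: ``codes[i]`` is the 2-bit packing of
    the window starting at 0-based offset ``positions[i]``.  Windows
    containing any non-ACGT letter are skipped entirely (positions stay
    global, so downstream coordinates are unaffected by skipping).
    Vectorized sliding-window evaluation; one pass over the sequence.
    """
    if k < 1 or k > 32:
        raise EncodingError(f"k={k} out of range 1..32")
    n = len(residues) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for ch, c in _CODE.items():
        lut[ord(ch)] = c
    codes2 = lut[raw]  # 255 marks non-ACGT
    valid = codes2 != 255
    # window is clean iff all k letters are valid
    win_valid = np.ones(n, dtype=bool)
    csum = np.concatenate(([0], np.cumsum(valid)))
    win_valid = (csum[k:] - csum[:-k]) == k
    # Horner accumulation of the packed code over the k letters
    acc = np.zeros(n, dtype=np.uint64)
    safe = np.where(valid, codes2, 0).astype(np.uint64)
    for j in range(k):
        acc = (acc << np.uint64(2)) | safe[j : j + n]
    positions = np.nonzero(win_valid)[0].astype(np.int64)
    return acc[win_valid], positions


def reverse_complement(seq: Sequence) -> Sequence:
    """Watson–Crick reverse complement; N maps to N.  Involution."""
    return Sequence(
        id=seq.id + "_rc",
        residues=seq.residues.translate(_COMPLEMENT)[::-1],
    )
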