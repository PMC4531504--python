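"""Prefix-partitioned k-mer dictionaries: build, persist, query, derive.

A dictionary records every clean K-letter window of one sequence together
with its 0-based occurrence positions, with entries in strictly ascending
word order.  Construction is split into ``p`` passes (p a power of 4): a
prefix of ``log4(p)`` letters partitions the word space, pass *i* scans the
sequence and collects only windows whose prefix has rank *i*, and passes
are emitted in prefix order so the concatenated output is globally sorted.
The point of the partitioning is the memory contract: at no time are more
than one partition's entries resident, so peak memory is bounded by the
densest partition rather than by the whole word space.

Because the word order is lexicographic and prefixes of a sorted list are
sorted, a single dictionary built at large K (default 32) contains every
shorter dictionary: :func:`words_at_length` merges adjacent entries that
share their first K' letters, losing only the last K-K' window positions
of the sequence.  Sensitivity studies over seed length therefore need one
dictionary build, not one per K'.

On-disk format (fixed-width little-endian, portable across platforms):

``<name>.words``     16-byte header (magic ``HSPD``, version u16, K u16,
                     entry count u64) followed by one 24-byte record per
                     entry: word code u64, occurrence count u64, element
                     offset into the positions file u64.
``<name>.positions`` concatenated occurrence positions, u64 each, in
                     entry order, ascending within an entry.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from hspscan.sequence_io import Sequence, decode_kmer, encode_windows

MAGIC = b"HSPD"
VERSION = 1
_HEADER = struct.Struct("<4sHHQ")  # magic, version, K, entry count
_RECORD_DTYPE = np.dtype([("code", "<u8"), ("count", "<u8"), ("offset", "<u8")])


class DictionaryFormatError(ValueError):
    """Raised when a persisted dictionary fails header or order validation."""


@dataclass
class Params:
    """Pipeline parameters shared across stages.

    K is the dictionary word length (the single large build); k_seed (K')
    is the seed word length actually used for hit enumeration, chosen per
    run from the same dictionary.  ``partitions`` is the number of prefix
    passes of the dictionary build and must be a power of 4 so the prefix
    length log4(p) is a whole number of letters.
    """

    k: int = 32
    k_seed: int = 16
    partitions: int = 16
    match: int = 4
    mismatch: int = 4
    proximity: int = 0          # 0 disables the proximity filter
    cap: int = 10_000           # max hits per shared word; 0 = unlimited
    min_length: int | None = None   # None -> defaults to k_seed
    min_score: int = 0          # exclusive: HSP score must be > min_score
    min_identity: float = 0.0   # percent; >= passes

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 32):
            raise ValueError(f"K={self.k} outside 1..32 (format reserves 64 bits/word)")
        if not (1 <= self.k_seed <= self.k):
            raise ValueError(f"K'={self.k_seed} must satisfy 1 <= K' <= K={self.k}")
        plen = prefix_length(self.partitions)
        if plen > self.k:
            raise ValueError(f"prefix length {plen} exceeds K={self.k}")
        if self.match <= 0 or self.mismatch <= 0:
            raise ValueError("match/mismatch weights must be positive")
        if self.proximity < 0 or self.cap < 0:
            raise ValueError("proximity distance and sampling cap must be >= 0")

    @property
    def effective_min_length(self) -> int:
        return self.k_seed if self.min_length is None else self.min_length


def prefix_length(partitions: int) -> int:
    """Letters in the partitioning prefix: log4(p), for p a power of 4."""
    if partitions < 1:
        raise ValueError("partition count must be >= 1")
    plen = round(math.log(partitions, 4))
    if 4**plen != partitions:
        raise ValueError(
            f"partition count {partitions} is not a power of 4 "
            "(an integer prefix length requires powers of 4)"
        )
    return plen


def enumerate_prefixes(partitions: int) -> list[int]:
    """Prefix ranks 0..p-1, i.e. all distinct log4(p)-letter prefixes in order."""
    prefix_length(partitions)  # validate
    return list(range(partitions))


@dataclass
class DictionaryEntry:
    """One distinct word and its ascending occurrence positions."""

    code: int
    k: int
    positions: np.ndarray  # int64, strictly increasing

    @property
    def word(self) -> str:
        return decode_kmer(self.code, self.k)

    @property
    def count(self) -> int:
        return int(self.positions.size)


@dataclass
class Dictionary:
    """Sorted k-mer dictionary held as flat arrays.

    ``codes`` are strictly ascending; entry *i* owns
    ``positions[offsets[i] : offsets[i] + counts[i]]``.
    """

    source_id: str
    k: int
    codes: np.ndarray      # uint64, strictly ascending
    counts: np.ndarray     # int64
    positions: np.ndarray  # int64, entry-major, ascending within each entry
    offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.offsets is None:
            self.offsets = np.concatenate(
                ([0], np.cumsum(self.counts[:-1]))
            ).astype(np.int64) if len(self.counts) else np.empty(0, np.int64)
        if self.codes.size > 1 and not np.all(self.codes[1:] > self.codes[:-1]):
            raise DictionaryFormatError("dictionary words are not strictly ascending")

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def total_occurrences(self) -> int:
        return int(self.positions.size)

    def entry(self, i: int) -> DictionaryEntry:
        o, c = int(self.offsets[i]), int(self.counts[i])
        return DictionaryEntry(int(self.codes[i]), self.k, self.positions[o : o + c])

    def entries(self) -> Iterator[DictionaryEntry]:
        for i in range(len(self)):
            yield self.entry(i)


def build_dictionary(
    seq: Sequence,
    params: Params | None = None,
    out: str | Path | None = None,
    name: str | None = None,
) -> Dictionary:
    """Build the sorted K-mer dictionary of ``seq`` in ``p`` prefix passes.

    Pass *i* re-scans the sequence and keeps only the clean windows whose
    leading ``log4(p)`` letters have rank *i*; within the pass windows are
    sorted by packed code (stably, so positions stay ascending per word)
    and grouped into entries.  Successive passes append in prefix order,
    which yields a globally sorted dictionary while holding at most one
    partition's entries in memory.

    If ``out`` is given the dictionary is also persisted there under
    ``name`` (default: the sequence id).
    """
    params = params or Params()
    k, p = params.k, params.partitions
    plen = prefix_length(p)
    shift = np.uint64(2 * (k - plen))

    part_codes: list[np.ndarray] = []
    part_counts: list[np.ndarray] = []
    part_positions: list[np.ndarray] = []
    for rank in range(p):
        # one full scan per pass, as the partition contract requires
        codes, positions = encode_windows(seq.residues, k)
        mask = (codes >> shift) == np.uint64(rank)
        codes, positions = codes[mask], positions[mask]
        order = np.argsort(codes, kind="stable")  # stable: positions ascend per code
        codes, positions = codes[order], positions[order]
        ucodes, counts = np.unique(codes, return_counts=True)
        part_codes.append(ucodes)
        part_counts.append(counts.astype(np.int64))
        part_positions.append(positions)

    d = Dictionary(
        source_id=seq.id,
        k=k,
        codes=np.concatenate(part_codes) if part_codes else np.empty(0, np.uint64),
        counts=np.concatenate(part_counts) if part_counts else np.empty(0, np.int64),
        positions=np.concatenate(part_positions)
        if part_positions
        else np.empty(0, np.int64),
    )
    if out is not None:
        write_dictionary(d, out, name=name)
    return d


def naive_dictionary(seq: Sequence, k: int) -> dict[str, list[int]]:
    """Reference dictionary built by hashing every window as a string.

    Deliberately independent of the packed/partitioned build path; used as
    the oracle in tests.  Returns {word: ascending positions}, clean
    windows only, in sorted word order.
    """
    table: dict[str, list[int]] = {}
    res = seq.residues
    for i in range(len(res) - k + 1):
        w = res[i : i + k]
        if set(w) <= {"A", "C", "G", "T"}:
            table.setdefault(w, []).append(i)
    return dict(sorted(table.items()))


def words_at_length(
    d: Dictionary, k_seed: int
) -> Iterator[tuple[int, np.ndarray]]:
    """Stream the K'-word view of a K-dictionary via the prefix property.

    Adjacent entries sharing their first K' letters merge into one; merged
    position lists are ascending.  Equals a directly built K' dictionary
    except for the last K-K' window positions of the sequence, which a
    K-window build cannot see.
    """
    if k_seed > d.k:
        raise ValueError(f"K'={k_seed} exceeds dictionary K={d.k}")
    if len(d) == 0:
        return
    shift = np.uint64(2 * (d.k - k_seed))
    prefix_codes = d.codes >> shift  # non-decreasing
    bounds = np.nonzero(np.diff(prefix_codes))[0] + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(d)]))
    for s, e in zip(starts, ends):
        lo, hi = int(d.offsets[s]), int(d.offsets[e - 1] + d.counts[e - 1])
        positions = d.positions[lo:hi]
        if e - s > 1:
            positions = np.sort(positions)
        yield int(prefix_codes[s]), positions


def write_dictionary(d: Dictionary, out: str | Path, name: str | None = None) -> Path:
    """Persist to ``<out>/<name>.words`` + ``.positions`` (little-endian)."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    stem = name if name is not None else d.source_id
    records = np.empty(len(d), dtype=_RECORD_DTYPE)
    records["code"] = d.codes
    records["count"] = d.counts.astype(np.uint64)
    records["offset"] = d.offsets.astype(np.uint64)
    with open(out / f"{stem}.words", "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, VERSION, d.k, len(d)))
        fh.write(records.tobytes())
    with open(out / f"{stem}.positions", "wb") as fh:
        fh.write(d.positions.astype("<u8").tobytes())
    return out / f"{stem}.words"


def load_dictionary(path: str | Path, name: str | None = None) -> Dictionary:
    """Load a persisted dictionary; validates magic, version, and sortedness.

    ``path`` may be the ``.words`` file itself or a directory (then
    ``name`` selects the stem; with exactly one ``.words`` file present it
    may be omitted).
    """
    path = Path(path)
    if path.is_dir():
        if name is not None:
            words_path = path / f"{name}.words"
        else:
            candidates = sorted(path.glob("*.words"))
            if len(candidates) != 1:
                raise DictionaryFormatError(
                    f"{path}: expected exactly one .words file, found {len(candidates)}"
                )
            words_path = candidates[0]
    else:
        words_path = path
    if not words_path.exists():
        raise FileNotFoundError(words_path)
    positions_path = words_path.with_suffix(".positions")

    raw = words_path.read_bytes()
    if len(raw) < _HEADER.size:
        raise DictionaryFormatError(f"{words_path}: truncated header")
    magic, version, k, n_entries = _HEADER.unpack_from(raw)
    if magic != MAGIC:
        raise DictionaryFormatError(f"{words_path}: bad magic {magic!r}")
    if version != VERSION:
        raise DictionaryFormatError(f"{words_path}: unsupported version {version}")
    body = raw[_HEADER.size :]
    expected = n_entries * _RECORD_DTYPE.itemsize
    if len(body) != expected:
        raise DictionaryFormatError(
            f"{words_path}: expected {expected} record bytes, found {len(body)}"
        )
    records = np.frombuffer(body, dtype=_RECORD_DTYPE)
    positions = np.frombuffer(positions_path.read_bytes(), dtype="<u8").astype(np.int64)
    total = int(records["count"].sum()) if n_entries else 0
    if positions.size != total:
        raise DictionaryFormatError(
            f"{positions_path}: {positions.size} positions, header implies {total}"
        )
    return Dictionary(
        source_id=words_path.stem,
        k=int(k),
        codes=records["code"].astype(np.uint64),
        counts=records["count"].astype(np.int64),
        positions=positions,
        offsets=records["offset"].astype(np.int64),
    )


def dict_stats(d: Dictionary) -> dict[str, float]:
    """Simple occurrence statistics used by the ``dict-stats`` subcommand."""
    if len(d) == 0:
        return {"entries": 0, "occurrences": 0, "min": 0, "max": 0, "mean": 0.0}
    return {
        "entries": len(d),
        "occurrences": d.total_occurrences,
        "min": int(d.counts.min()),
        "max": int(d.counts.max()),
        "mean": float(d.counts.mean()),
    }
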