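"""Seed-hit enumeration, diagonal sorting, proximity thinning, repeat sampling.

A hit is a coordinate pair (x, y) at which identical K'-letter words occur
in both sequences; its diagonal is d = x - y.  If a shared word occurs n
times in X and m times in Y, the full cross product contributes n*m hits.
Hits are kept as a flat structured array with fields ``d, x, y`` and are
processed sorted by (d, x) — ties are impossible since (d, x) determines
(x, y).

Two thinning devices bound the quadratic blow-up that repeats cause:

* per-word sampling — when one shared word yields more than ``cap`` hits,
  only ``cap`` equally spaced ranks of its cross product are kept, so a
  low-complexity repeat still seeds extension but no longer dominates it;
* proximity combining — on each diagonal, a hit closer than ``distance``
  to the previously kept hit collapses into it (the earliest seed of the
  cluster survives and triggers the same extension).
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Iterator

import numpy as np

from hspscan.dictionary import Dictionary, words_at_length

HIT_DTYPE = np.dtype([("d", "<i8"), ("x", "<i8"), ("y", "<i8")])

_HITS_MAGIC = b"HSPH"
_HITS_HEADER = struct.Struct("<4sHHQ")  # magic, version, K', hit count
_HITS_RECORD = np.dtype([("d", "<i8"), ("x", "<u8")])


class HitsFormatError(ValueError):
    pass


def hits_array(x, y) -> np.ndarray:
    """Assemble a hits array from coordinate vectors; d = x - y."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    out = np.empty(x.size, dtype=HIT_DTYPE)
    out["x"], out["y"], out["d"] = x, y, x - y
    return out


def sample_ranks(n_hits: int, cap: int) -> np.ndarray:
    """Ranks kept from a cross product of ``n_hits``, at most ``cap`` of them.

    Equally spaced: rank t -> floor(t * (n_hits - 1) / (cap - 1)) for
    t = 0..cap-1, so the first and last pair always survive.  cap = 0
    disables sampling; cap = 1 keeps only the first pair.
    """
    if cap == 0 or n_hits <= cap:
        return np.arange(n_hits, dtype=np.int64)
    if cap == 1:
        return np.zeros(1, dtype=np.int64)
    t = np.arange(cap, dtype=np.int64)
    return t * (n_hits - 1) // (cap - 1)


def _merge_join(
    stream_x: Iterator[tuple[int, np.ndarray]],
    stream_y: Iterator[tuple[int, np.ndarray]],
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (positions_in_X, positions_in_Y) for every shared word code."""
    item_x = next(stream_x, None)
    item_y = next(stream_y, None)
    while item_x is not None and item_y is not None:
        cx, px = item_x
        cy, py = item_y
        if cx < cy:
            item_x = next(stream_x, None)
        elif cy < cx:
            item_y = next(stream_y, None)
        else:
            yield px, py
            item_x = next(stream_x, None)
            item_y = next(stream_y, None)


def generate_hits(
    dict_x: Dictionary,
    dict_y: Dictionary,
    k_seed: int,
    cap: int = 0,
) -> np.ndarray:
    """All seed hits at word length K', by sorted merge-join of the two
    K'-word streams derived from the K dictionaries.

    For each shared word with n occurrences in X and m in Y the full n*m
    cross product is emitted, enumerated X-major (all Y partners of the
    first X occurrence, then of the second, ...), optionally thinned per
    word by :func:`sample_ranks`.  Output order is word order, not (d, x);
    sort with :func:`sort_hits` before filtering or extension.
    """
    if dict_x.k != dict_y.k:
        raise ValueError(f"dictionary K mismatch: {dict_x.k} vs {dict_y.k}")
    if k_seed > dict_x.k:
        raise ValueError(f"K'={k_seed} exceeds dictionary K={dict_x.k}")
    chunks = []
    for px, py in _merge_join(
        words_at_length(dict_x, k_seed), words_at_length(dict_y, k_seed)
    ):
        n, m = px.size, py.size
        ranks = sample_ranks(n * m, cap)
        # rank r in X-major enumeration -> pair (px[r // m], py[r % m])
        x = px[ranks // m]
        y = py[ranks % m]
        chunks.append(hits_array(x, y))
    if not chunks:
        return np.empty(0, dtype=HIT_DTYPE)
    return np.concatenate(chunks)


def sort_hits(hits: np.ndarray) -> np.ndarray:
    """Order by (diagonal ascending, x ascending) — a total order on hits."""
    order = np.lexsort((hits["x"], hits["d"]))
    return hits[order]


def _check_sorted(hits: np.ndarray) -> None:
    if hits.size < 2:
        return
    d, x = hits["d"], hits["x"]
    ok = (d[1:] > d[:-1]) | ((d[1:] == d[:-1]) & (x[1:] > x[:-1]))
    if not bool(ok.all()):
        raise ValueError("hits are not sorted by (diagonal, x); call sort_hits first")


def filter_proximity(hits: np.ndarray, distance: int) -> np.ndarray:
    """Collapse clusters of nearby hits on the same diagonal.

    Scanning each diagonal in x order, a hit is dropped when its x lies
    within ``distance`` of the x of the last *kept* hit on that diagonal;
    the earliest hit of every cluster survives.  The filter never crosses
    diagonals.  distance = 0 keeps everything.
    """
    _check_sorted(hits)
    if distance == 0 or hits.size == 0:
        return hits
    keep = np.ones(hits.size, dtype=bool)
    last_d = None
    last_x = 0
    for i in range(hits.size):
        d, x = int(hits["d"][i]), int(hits["x"][i])
        if d == last_d and x - last_x <= distance:
            keep[i] = False
        else:
            last_d, last_x = d, x
    return hits[keep]


def write_hits(hits: np.ndarray, path: str | Path, k_seed: int) -> None:
    """Persist hits as fixed-width little-endian (d: i64, x: u64) records,
    so the seeding stage can be re-run or inspected independently."""
    records = np.empty(hits.size, dtype=_HITS_RECORD)
    records["d"] = hits["d"]
    records["x"] = hits["x"].astype(np.uint64)
    with open(path, "wb") as fh:
        fh.write(_HITS_HEADER.pack(_HITS_MAGIC, 1, k_seed, hits.size))
        fh.write(records.tobytes())


def load_hits(path: str | Path) -> tuple[np.ndarray, int]:
    """Load a hits file; returns (hits, K')."""
    raw = Path(path).read_bytes()
    if len(raw) < _HITS_HEADER.size:
        raise HitsFormatError(f"{path}: truncated header")
    magic, version, k_seed, count = _HITS_HEADER.unpack_from(raw)
    if magic != _HITS_MAGIC or version != 1:
        raise HitsFormatError(f"{path}: bad magic/version")
    body = raw[_HITS_HEADER.size :]
    if len(body) != count * _HITS_RECORD.itemsize:
        raise HitsFormatError(f"{path}: truncated records")
    records = np.frombuffer(body, dtype=_HITS_RECORD)
    x = records["x"].astype(np.int64)
    d = records["d"]
    return hits_array(x, x - d), int(k_seed)
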