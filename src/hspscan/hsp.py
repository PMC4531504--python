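"""Maximal ungapped HSP extension with coverage skipping, on both strands.

An HSP (high-scoring segment pair) is an ungapped local alignment
fragment whose positive accumulated score cannot be increased by
extending or trimming either end.  Extension starts from a seed hit —
a K'-column exact match, so the running score starts positive at
K' * match_weight — and walks outward in each direction, adding the
match weight for an identical column and subtracting the mismatch weight
otherwise, until the running score drops below zero or a sequence end is
reached.  Each boundary is the column at which the running score attained
its maximum (ties broken toward the seed, which trims zero-score tails).

Hits are consumed sorted by (diagonal, x).  A hit that falls inside the
span of the previously accepted HSP on the same diagonal is skipped
without extension: it could only reproduce a redundant sub-fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hspscan.dictionary import Params, build_dictionary
from hspscan.seeding import filter_proximity, generate_hits, sort_hits
from hspscan.sequence_io import Sequence, reverse_complement


@dataclass(frozen=True)
class HSP:
    """One ungapped fragment.  Coordinates are 0-based inclusive.

    ``y_start``/``y_end`` are expressed on Y's forward strand: for a
    forward fragment y ascends with x; for a reverse fragment y descends
    (y_start > y_end) because the match runs along the complement.
    """

    x_start: int
    x_end: int
    y_start: int
    y_end: int
    strand: str  # 'f' or 'r'
    length: int
    score: int
    identity: float  # percent of matching columns

    def __post_init__(self) -> None:
        if self.strand not in ("f", "r"):
            raise ValueError(f"strand must be 'f' or 'r', got {self.strand!r}")
        if self.length != self.x_end - self.x_start + 1:
            raise ValueError("length inconsistent with x coordinates")
        y_span = (
            self.y_end - self.y_start + 1
            if self.strand == "f"
            else self.y_start - self.y_end + 1
        )
        if y_span != self.length:
            raise ValueError("length inconsistent with y coordinates")

    @property
    def diagonal(self) -> int:
        """x_start - y_start; constant along the fragment only for strand 'f'."""
        return self.x_start - self.y_start


def _match(a: str, b: str) -> bool:
    # N never matches anything, including N
    return a == b and a != "N"


def _extend_raw(
    xres: str,
    yres: str,
    x: int,
    y: int,
    k_seed: int,
    match: int,
    mismatch: int,
) -> tuple[int, int, int, int]:
    """Extend a seed at (x, y); returns (x_start, x_end, score, matches).

    ``yres`` is the strand-resolved residue string of Y: for a reverse
    comparison pass it is already the reverse complement, so coordinates
    here are always forward along both strings.
    """
    lx, ly = len(xres), len(yres)
    if not (0 <= x <= lx - k_seed and 0 <= y <= ly - k_seed):
        raise ValueError(f"hit ({x},{y}) out of bounds for K'={k_seed}")
    seed_score = k_seed * match

    # forward: from the seed's last column rightward
    running = seed_score
    best = seed_score
    x_end = x + k_seed - 1
    i = 1
    while x + k_seed - 1 + i < lx and y + k_seed - 1 + i < ly:
        if _match(xres[x + k_seed - 1 + i], yres[y + k_seed - 1 + i]):
            running += match
        else:
            running -= mismatch
        if running > best:
            best = running
            x_end = x + k_seed - 1 + i
        if running < 0:
            break
        i += 1
    best_fwd = best

    # backward: from the seed's first column leftward, from the seed score alone
    running = seed_score
    best = seed_score
    x_start = x
    i = 1
    while x - i >= 0 and y - i >= 0:
        if _match(xres[x - i], yres[y - i]):
            running += match
        else:
            running -= mismatch
        if running > best:
            best = running
            x_start = x - i
        if running < 0:
            break
        i += 1
    best_bwd = best

    score = best_fwd + best_bwd - seed_score
    length = x_end - x_start + 1
    d = x - y
    matches = sum(
        1 for j in range(x_start, x_end + 1) if _match(xres[j], yres[j - d])
    )
    assert score == matches * match - (length - matches) * mismatch
    return x_start, x_end, score, matches


def extend_hit(
    x_seq: Sequence,
    y_seq: Sequence,
    x: int,
    y: int,
    params: Params,
    strand: str = "f",
) -> HSP | None:
    """Extend one hit to a maximal ungapped fragment.

    ``y_seq`` must already be strand-resolved (the reverse complement for
    strand 'r'); coordinates are on that resolved string and are mapped
    back to forward-Y by :func:`_map_strand`.  Returns ``None`` only when
    the fragment fails the report thresholds.
    """
    x_start, x_end, score, matches = _extend_raw(
        x_seq.residues, y_seq.residues, x, y,
        params.k_seed, params.match, params.mismatch,
    )
    length = x_end - x_start + 1
    identity = 100.0 * matches / length
    if length < params.effective_min_length:
        return None
    if score <= params.min_score:
        return None
    if identity < params.min_identity:
        return None
    d = x - y
    return _map_strand(
        x_start, x_end, x_start - d, x_end - d,
        strand, len(y_seq), length, score, identity,
    )


def _map_strand(
    x_start: int, x_end: int, y_start: int, y_end: int,
    strand: str, ly: int, length: int, score: int, identity: float,
) -> HSP:
    if strand == "r":
        # back onto forward-Y offsets: y_fwd = Ly - 1 - y_rev
        y_start, y_end = ly - 1 - y_start, ly - 1 - y_end
    return HSP(x_start, x_end, y_start, y_end, strand, length, score, identity)


def detect_hsps(
    x_seq: Sequence,
    y_seq: Sequence,
    hits: np.ndarray,
    params: Params,
    strand: str = "f",
    stats: dict | None = None,
) -> list[HSP]:
    """Extend sorted, filtered hits into HSPs with per-diagonal coverage
    skipping.

    Hits must be sorted by (d, x).  A hit whose diagonal equals that of
    the last accepted HSP and whose x lies at or before that HSP's x_end
    is skipped without extension.  ``stats`` (if given) accumulates
    ``hits_seen``, ``hits_skipped`` and ``extensions`` counters — the
    instrumentation surface for the repeat-sampling tests.
    Output is sorted by (diagonal, x_start).
    """
    out: list[HSP] = []
    last_d: int | None = None
    last_x_end = -1
    for i in range(hits.size):
        d, x, y = int(hits["d"][i]), int(hits["x"][i]), int(hits["y"][i])
        if stats is not None:
            stats["hits_seen"] = stats.get("hits_seen", 0) + 1
        if d == last_d and x <= last_x_end:
            if stats is not None:
                stats["hits_skipped"] = stats.get("hits_skipped", 0) + 1
            continue
        if stats is not None:
            stats["extensions"] = stats.get("extensions", 0) + 1
        hsp = extend_hit(x_seq, y_seq, x, y, params, strand=strand)
        if hsp is not None:
            out.append(hsp)
            last_d = d
            last_x_end = hsp.x_end
    return out


def compare_sequences(
    x_seq: Sequence,
    y_seq: Sequence,
    params: Params,
    strand: str = "f",
    dict_x=None,
    dict_y=None,
    stats: dict | None = None,
) -> list[HSP]:
    """Full single-strand pipeline: dictionaries -> hits -> sort ->
    proximity filter -> extension.  ``y_seq`` must be strand-resolved."""
    if dict_x is None:
        dict_x = build_dictionary(x_seq, params)
    if dict_y is None:
        dict_y = build_dictionary(y_seq, params)
    hits = generate_hits(dict_x, dict_y, params.k_seed, cap=params.cap)
    hits = sort_hits(hits)
    if stats is not None:
        stats["hits_raw"] = stats.get("hits_raw", 0) + int(hits.size)
    hits = filter_proximity(hits, params.proximity)
    if stats is not None:
        stats["hits_filtered"] = stats.get("hits_filtered", 0) + int(hits.size)
    return detect_hsps(x_seq, y_seq, hits, params, strand=strand, stats=stats)


def compare_both_strands(
    x_seq: Sequence,
    y_seq: Sequence,
    params: Params,
    stats: dict | None = None,
) -> list[HSP]:
    """Run the pipeline on (X, Y) forward and on (X, revcomp(Y)) reverse.

    Reverse-strand fragments report y on Y's forward strand with
    y_start > y_end, so dotplots show them as anti-diagonal segments.
    """
    forward = compare_sequences(x_seq, y_seq, params, strand="f", stats=stats)
    y_rc = reverse_complement(y_seq)
    reverse = compare_sequences(x_seq, y_rc, params, strand="r", stats=stats)
    return forward + reverse
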