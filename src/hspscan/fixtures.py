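"""Synthetic sequence pairs with known homology structure.

Every pipeline stage is testable without external data: this module
generates random backgrounds, plants copies of chosen X intervals into Y
— forward or reverse-complemented, mutated by per-column substitution to
a target identity — and returns a ground-truth table of the planted
coordinates.  Mutations are substitutions only, so planted segments stay
on one diagonal and ungapped recovery is well defined; tandem repeats can
be planted separately to exercise the seed-sampling path.

All generation is reproducible from explicit integer seeds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hspscan.hsp import HSP
from hspscan.sequence_io import Sequence, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSegment:
    """One planted homologous segment, 0-based inclusive coordinates.

    ``y_start <= y_end`` always (forward-Y interval); ``strand`` records
    whether the copy was reverse-complemented before insertion.
    """

    x_start: int
    x_end: int
    y_start: int
    y_end: int
    strand: str
    identity: float  # target percent identity of the planted copy

    @property
    def length(self) -> int:
        return self.x_end - self.x_start + 1


@dataclass
class PlantedTruth:
    segments: list[PlantedSegment] = field(default_factory=list)
    seed: int = 0

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["xStart", "xEnd", "yStart", "yEnd", "strand", "identity"])
            for s in self.segments:
                writer.writerow(
                    [s.x_start + 1, s.x_end + 1, s.y_start + 1, s.y_end + 1,
                     s.strand, f"{s.identity:.4f}"]
                )
        return path

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = 0) -> "PlantedTruth":
        segments = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)
            for row in reader:
                segments.append(
                    PlantedSegment(
                        int(row[0]) - 1, int(row[1]) - 1,
                        int(row[2]) - 1, int(row[3]) - 1,
                        row[4], float(row[5]),
                    )
                )
        return cls(segments=segments, seed=seed)


def random_sequence(
    length: int, gc: float = 0.5, seed: int = 0, id: str = "synthetic"
) -> Sequence:
    """Uniform i.i.d. DNA at the given GC fraction; reproducible per seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at, cg = (1.0 - gc) / 2.0, gc / 2.0
    idx = rng.choice(4, size=length, p=[at, cg, cg, at])  # A, C, G, T
    return Sequence(id=id, residues=_BASES[idx].tobytes().decode("ascii"))


def _mutate(residues: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute each column independently with probability 1 - identity."""
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < (1.0 - identity / 100.0)
    if hit.any():
        # replace with a uniformly chosen *different* base
        idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def plant_homology(
    x_seq: Sequence,
    segments: list[tuple[int, float, str]],
    seed: int,
    background: int = 500,
    gc: float = 0.5,
) -> tuple[Sequence, PlantedTruth]:
    """Build Y as random background interleaved with mutated copies of X
    intervals.

    ``segments`` lists (length, target identity percent, strand).  Source
    intervals are drawn left-to-right from X without overlap; each copy
    is substitution-mutated to the target identity, reverse-complemented
    for strand 'r', and inserted between background stretches of
    ``background`` bp.  Returns (Y, truth table in forward-Y coords).
    """
    rng = np.random.default_rng(seed)
    total = sum(length for length, _, _ in segments)
    slack = len(x_seq) - total
    if slack < 0:
        raise ValueError("planted segments do not fit in X")
    n = len(segments)

    # non-overlapping source intervals, left to right, random spacing
    gaps = rng.multinomial(slack, np.ones(n + 1) / (n + 1)) if n else []
    x_cursor = 0
    sources: list[tuple[int, int]] = []
    for (length, _, _), gap in zip(segments, gaps):
        x_cursor += int(gap)
        sources.append((x_cursor, x_cursor + length - 1))
        x_cursor += length

    parts: list[str] = []
    truth = PlantedTruth(seed=seed)
    y_cursor = 0
    for (length, identity, strand), (xs, xe) in zip(segments, sources):
        bg = random_sequence(background, gc=gc, seed=int(rng.integers(2**31)))
        parts.append(bg.residues)
        y_cursor += background
        copy = _mutate(x_seq.residues[xs : xe + 1], identity, rng)
        if strand == "r":
            copy = reverse_complement(Sequence(id="tmp", residues=copy)).residues
        parts.append(copy)
        truth.segments.append(
            PlantedSegment(xs, xe, y_cursor, y_cursor + length - 1, strand, identity)
        )
        y_cursor += length
    tail = random_sequence(background, gc=gc, seed=int(rng.integers(2**31)))
    parts.append(tail.residues)
    y = Sequence(id=x_seq.id + "_planted", residues="".join(parts))
    return y, truth


def plant_repeats(
    x_seq: Sequence, motif: str, copies: int, seed: int
) -> tuple[Sequence, tuple[int, int]]:
    """Insert ``copies`` tandem copies of ``motif`` at a random locus.

    Returns the modified sequence and the 0-based inclusive locus of the
    inserted repeat block.  A block of c copies of an m-mer contains
    c*m - k + 1 identical-word windows for k <= m, so planting the same
    block in both sequences creates a shared word whose cross product
    grows quadratically — the input that hit sampling exists for.
    """
    if set(motif) - {"A", "C", "G", "T"}:
        raise ValueError("motif must be over {A,C,G,T}")
    rng = np.random.default_rng(seed)
    insert_at = int(rng.integers(0, len(x_seq) + 1))
    block = motif * copies
    residues = x_seq.residues[:insert_at] + block + x_seq.residues[insert_at:]
    locus = (insert_at, insert_at + len(block) - 1)
    return Sequence(id=x_seq.id + "_rep", residues=residues), locus


def _hsp_x_interval_in_segment(h: HSP, s: PlantedSegment) -> tuple[int, int]:
    """X-interval of HSP columns whose (x, y) both fall inside segment s.

    Empty intervals are returned as (1, 0).  Only same-strand pairs can
    overlap; columns are constrained on x directly and on y through the
    fragment's diagonal (forward: y = x - d; reverse: y = c - x).
    """
    if h.strand != s.strand:
        return (1, 0)
    lo, hi = max(h.x_start, s.x_start), min(h.x_end, s.x_end)
    if h.strand == "f":
        d = h.x_start - h.y_start
        lo = max(lo, s.y_start + d)
        hi = min(hi, s.y_end + d)
    else:
        c = h.x_start + h.y_start  # y = c - x along a reverse fragment
        lo = max(lo, c - s.y_end)
        hi = min(hi, c - s.y_start)
    return (lo, hi) if lo <= hi else (1, 0)


def evaluate_recovery(
    hsps: list[HSP], truth: PlantedTruth
) -> dict[str, float | list[float]]:
    """Column-level recovery of planted segments by reported HSPs.

    ``coverage``: per segment, the fraction of its columns overlapped by
    at least one HSP column (x and y both inside, strand matching).
    ``specificity``: the fraction of all reported HSP columns that fall
    inside some planted segment.
    """
    coverages: list[float] = []
    for s in truth.segments:
        covered = np.zeros(s.length, dtype=bool)
        for h in hsps:
            lo, hi = _hsp_x_interval_in_segment(h, s)
            if lo <= hi:
                covered[lo - s.x_start : hi - s.x_start + 1] = True
        coverages.append(float(covered.mean()))
    total_cols = sum(h.length for h in hsps)
    inside = 0
    for h in hsps:
        for s in truth.segments:
            lo, hi = _hsp_x_interval_in_segment(h, s)
            if lo <= hi:
                inside += hi - lo + 1
    specificity = inside / total_cols if total_cols else 1.0
    return {
        "coverage": coverages,
        "min_coverage": min(coverages) if coverages else 1.0,
        "mean_coverage": float(np.mean(coverages)) if coverages else 1.0,
        "specificity": float(specificity),
    }
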