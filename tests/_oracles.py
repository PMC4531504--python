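"""Independent reference implementations used as test oracles.

These deliberately avoid the package's packed-code / merge-join /
running-walk code paths: seeds are found by comparing window *strings*,
and extension is formulated as cumulative sums over a per-diagonal score
vector.  They are shared by the unit tests, the acceptance tests, and
scripts/acceptance.py.
"""

from __future__ import annotations

import numpy as np

ACGT = {"A", "C", "G", "T"}


def brute_hits_quadratic(xres: str, yres: str, k: int) -> list[tuple[int, int]]:
    """Literal O(Lx*Ly) window comparison; use only on short sequences."""
    out = []
    for i in range(len(xres) - k + 1):
        wx = xres[i : i + k]
        if set(wx) <= ACGT:
            for j in range(len(yres) - k + 1):
                if yres[j : j + k] == wx:
                    out.append((i, j))
    return out


def brute_hits(xres: str, yres: str, k: int) -> list[tuple[int, int]]:
    """All (x, y) with identical clean k-windows, via a string-keyed join."""
    index: dict[str, list[int]] = {}
    for j in range(len(yres) - k + 1):
        w = yres[j : j + k]
        if set(w) <= ACGT:
            index.setdefault(w, []).append(j)
    out = []
    for i in range(len(xres) - k + 1):
        w = xres[i : i + k]
        if set(w) <= ACGT:
            for j in index.get(w, ()):
                out.append((i, j))
    return out


class DiagonalScores:
    """Per-diagonal +match/-mismatch column score vectors, cached."""

    def __init__(self, xres: str, yres: str, match: int, mismatch: int):
        self.x = np.frombuffer(xres.encode(), dtype=np.uint8)
        self.y = np.frombuffer(yres.encode(), dtype=np.uint8)
        self.match, self.mismatch = match, mismatch
        self._cache: dict[int, tuple[int, np.ndarray]] = {}

    def get(self, d: int) -> tuple[int, np.ndarray]:
        """(x offset of first diagonal column, score per column)."""
        if d not in self._cache:
            lo = max(0, d)
            hi = min(self.x.size, self.y.size + d)
            xs = self.x[lo:hi]
            ys = self.y[lo - d : hi - d]
            is_match = (xs == ys) & (xs != ord("N"))
            scores = np.where(is_match, self.match, -self.mismatch).astype(np.int64)
            self._cache[d] = (lo, scores)
        return self._cache[d]


def _directional(run: np.ndarray, seed_score: int) -> tuple[int, int]:
    """(best running score, 1-based step count to its earliest position).

    ``run`` holds seed_score + cumsum of per-column scores away from the
    seed; the scan stops after the first column whose running score is
    negative.  Returns (seed_score, 0) when no column improves on it.
    """
    if run.size == 0:
        return seed_score, 0
    neg = np.nonzero(run < 0)[0]
    scanned = run[: neg[0]] if neg.size else run
    if scanned.size == 0 or scanned.max() <= seed_score:
        return seed_score, 0
    t = int(np.argmax(scanned))  # first occurrence = earliest column
    return int(scanned[t]), t + 1


def oracle_extend(
    ds: DiagonalScores, x: int, y: int, k: int
) -> tuple[int, int, int, int, int]:
    """Maximal ungapped fragment from seed (x, y); returns
    (x_start, x_end, y_start, y_end, score)."""
    d = x - y
    lo, scores = ds.get(d)
    seed_lo, seed_hi = x - lo, x + k - 1 - lo
    seed_score = k * ds.match

    fwd = scores[seed_hi + 1 :]
    best_f, steps_f = _directional(seed_score + np.cumsum(fwd), seed_score)
    bwd = scores[:seed_lo][::-1]
    best_b, steps_b = _directional(seed_score + np.cumsum(bwd), seed_score)

    xs = lo + seed_lo - steps_b
    xe = lo + seed_hi + steps_f
    return xs, xe, xs - d, xe - d, best_f + best_b - seed_score


def oracle_hsps(
    xres: str,
    yres: str,
    k: int,
    match: int,
    mismatch: int,
    hits: list[tuple[int, int]] | None = None,
) -> set[tuple[int, int, int, int, int]]:
    """Distinct maximal fragments from seeding at *every* exact k-match.

    No coverage skipping: redundant seeds reproduce the same fragment and
    collapse in the set, so this is the ground truth that coverage
    skipping must not fall short of.
    """
    if hits is None:
        hits = brute_hits(xres, yres, k)
    ds = DiagonalScores(xres, yres, match, mismatch)
    return {oracle_extend(ds, x, y, k) for x, y in hits}


def naive_kmer_positions(res: str, k: int) -> dict[str, list[int]]:
    """{word: ascending positions} over clean windows, by string hashing."""
    table: dict[str, list[int]] = {}
    for i in range(len(res) - k + 1):
        w = res[i : i + k]
        if set(w) <= ACGT:
            table.setdefault(w, []).append(i)
    return dict(sorted(table.items()))
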