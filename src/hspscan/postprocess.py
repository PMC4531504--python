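"""HSP post-processing: filters, collinear chaining, dotplots, converters.

The comparison stages emit ungapped fragments; this module turns them
into reportable artifacts.  Filtering applies report thresholds after the
fact (>= passes).  Chaining assembles collinear same-strand fragments
into simple gapped constructions with a greedy rule: walking fragments in
x order, a fragment joins the open chain when both its x-gap and y-gap to
the chain tail lie in [0, max_gap]; gaps are not penalized.  Dotplots
draw each fragment as a scaled line segment, red for forward strand and
black for reverse, X horizontal and Y vertical.

HSP tables are exchanged as CSV with header
``xStart,yStart,xEnd,yEnd,strand,length,score,identity`` using 1-based
inclusive coordinates (internal coordinates are 0-based).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as Seq

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from hspscan.hsp import HSP

_CSV_HEADER = ["xStart", "yStart", "xEnd", "yEnd", "strand", "length", "score", "identity"]

DIALECTS = ("csv", "tsv-coords", "bed-like")


@dataclass
class GappedFragment:
    """An ordered chain of collinear same-strand HSPs.

    ``gap_columns`` counts, summed over junctions, the larger of the two
    axis gaps — the number of columns a gapped alignment would need to
    insert to bridge the junction.  Gaps carry no score penalty.
    """

    members: list[HSP] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.members[0].strand

    @property
    def aligned_columns(self) -> int:
        return sum(h.length for h in self.members)

    @property
    def score(self) -> int:
        return sum(h.score for h in self.members)

    @property
    def x_start(self) -> int:
        return self.members[0].x_start

    @property
    def x_end(self) -> int:
        return self.members[-1].x_end

    @property
    def gap_columns(self) -> int:
        total = 0
        for a, b in zip(self.members, self.members[1:]):
            gx, gy = _gaps(a, b)
            total += max(gx, gy)
        return total


def filter_hsps(
    hsps: Iterable[HSP],
    min_length: int = 0,
    min_score: int = 0,
    min_identity: float = 0.0,
) -> list[HSP]:
    """Keep exactly the HSPs meeting every threshold (>= passes); order kept."""
    return [
        h
        for h in hsps
        if h.length >= min_length and h.score >= min_score and h.identity >= min_identity
    ]


def _gaps(a: HSP, b: HSP) -> tuple[int, int]:
    """(x gap, y gap) between consecutive fragments a -> b on one strand."""
    gx = b.x_start - a.x_end - 1
    if a.strand == "f":
        gy = b.y_start - a.y_end - 1
    else:
        gy = a.y_end - b.y_start - 1  # y descends on the reverse strand
    return gx, gy


def chain_hsps(hsps: Seq[HSP], max_gap: int) -> list[GappedFragment]:
    """Greedy collinear chaining of one strand's HSPs.

    Fragments are taken in (x_start, y_start) order; each joins the open
    chain iff both axis gaps to the chain tail are within [0, max_gap],
    otherwise it opens a new chain.  Every input HSP lands in exactly one
    chain.
    """
    strands = {h.strand for h in hsps}
    if len(strands) > 1:
        raise ValueError("chain_hsps expects HSPs from a single strand")
    ordered = sorted(hsps, key=lambda h: (h.x_start, h.y_start))
    chains: list[GappedFragment] = []
    for h in ordered:
        if chains:
            tail = chains[-1].members[-1]
            gx, gy = _gaps(tail, h)
            if 0 <= gx <= max_gap and 0 <= gy <= max_gap:
                chains[-1].members.append(h)
                continue
        chains.append(GappedFragment(members=[h]))
    return chains


def _draw(ax, hsps: Iterable[HSP], lx: int, ly: int) -> None:
    for h in hsps:
        color = "red" if h.strand == "f" else "black"
        ax.plot(
            [h.x_start, h.x_end], [h.y_start, h.y_end],
            color=color, linewidth=1.0, solid_capstyle="butt",
        )
    ax.set_xlim(0, lx)
    ax.set_ylim(0, ly)


def render_dotplot(
    hsps: Iterable[HSP],
    lx: int,
    ly: int,
    out: str | Path,
    width_px: int = 1000,
    title: str | None = None,
) -> Path:
    """Write a PNG dotplot: X horizontal, Y vertical, forward fragments
    red, reverse fragments black.  Height scales with Ly/Lx."""
    if lx <= 0 or ly <= 0:
        raise ValueError("sequence lengths must be positive")
    dpi = 100
    w = width_px / dpi
    h = max(2.0, w * ly / lx)
    fig, ax = plt.subplots(figsize=(w, h), dpi=dpi)
    _draw(ax, hsps, lx, ly)
    ax.set_xlabel("X position (bp)")
    ax.set_ylabel("Y position (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, format="png")
    plt.close(fig)
    return out


def project_multi(
    comparisons: Seq[tuple[str, Seq[HSP], int, int]],
    lx: int,
    out: str | Path,
    width_px: int = 1000,
) -> Path:
    """Stacked dotplot tracks over a common reference X.

    ``comparisons`` is a list of (label, hsps, lx_i, ly_i); every lx_i
    must equal the shared reference length ``lx``.  One track per
    comparison, in input order, sharing the X axis.
    """
    if not comparisons:
        raise ValueError("no comparisons to project")
    for label, _, lx_i, _ in comparisons:
        if lx_i != lx:
            raise ValueError(
                f"comparison {label!r} has reference length {lx_i}, expected {lx}"
            )
    dpi = 100
    n = len(comparisons)
    fig, axes = plt.subplots(
        n, 1, figsize=(width_px / dpi, max(2.0, 2.5 * n)), dpi=dpi,
        sharex=True, squeeze=False,
    )
    for ax, (label, hsps, _, ly_i) in zip(axes[:, 0], comparisons):
        _draw(ax, hsps, lx, ly_i)
        ax.set_ylabel(label)
    axes[-1, 0].set_xlabel("reference position (bp)")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, format="png")
    plt.close(fig)
    return out


def _format_row(h: HSP) -> list[str]:
    # 1-based inclusive coordinates in files
    return [
        str(h.x_start + 1), str(h.y_start + 1),
        str(h.x_end + 1), str(h.y_end + 1),
        h.strand, str(h.length), str(h.score), f"{h.identity:.4f}",
    ]


def write_hsps_csv(hsps: Iterable[HSP], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_HEADER)
        for h in hsps:
            writer.writerow(_format_row(h))
    return path


def load_hsps_csv(path: str | Path) -> list[HSP]:
    out: list[HSP] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != _CSV_HEADER:
            raise ValueError(f"{path}: unexpected CSV header {header}")
        for row in reader:
            xs, ys, xe, ye = (int(v) - 1 for v in row[:4])
            out.append(
                HSP(
                    x_start=xs, y_start=ys, x_end=xe, y_end=ye,
                    strand=row[4], length=int(row[5]), score=int(row[6]),
                    identity=float(row[7]),
                )
            )
    return out


def export_hsps(
    hsps: Iterable[HSP], dialect: str, path: str | Path, x_name: str = "X"
) -> Path:
    """Write an HSP table in one of the documented dialects.

    ``csv``        the native table (1-based inclusive, header).
    ``tsv-coords`` same eight fields, tab-separated, header line first.
    ``bed-like``   0-based half-open intervals on X:
                   x_name, start, end, name(strand), score.
    """
    path = Path(path)
    if dialect == "csv":
        return write_hsps_csv(hsps, path)
    if dialect == "tsv-coords":
        with open(path, "w") as fh:
            fh.write("\t".join(_CSV_HEADER) + "\n")
            for h in hsps:
                fh.write("\t".join(_format_row(h)) + "\n")
        return path
    if dialect == "bed-like":
        with open(path, "w") as fh:
            for i, h in enumerate(hsps):
                fh.write(
                    f"{x_name}\t{h.x_start}\t{h.x_end + 1}\t"
                    f"hsp{i}({h.strand})\t{h.score}\n"
                )
        return path
    raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
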