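"""Promoter CpG-island prediction.

A CpG island (CGI) is called with the classic vertebrate criteria: a
sliding window of ``window_len`` bases qualifies when its G+C fraction is
at least ``gc_min`` and its observed/expected CpG ratio

    O/E = (N_CpG * L) / (N_C * N_G)

is at least ``oe_min``. A position is *covered* when at least one
qualifying window overlaps it; islands are maximal runs of covered
positions whose whole-span statistics still pass both thresholds and
whose length reaches ``min_island_len``. Windows containing soft-masked
(lowercase) or ``N`` bases never qualify.

Promoter windows span ``upstream`` bases transcriptionally upstream to
``downstream`` bases downstream of each transcript 5' end (TSS),
mirrored on the minus strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, write_bed6

__all__ = [
    "CgiParams",
    "PromoterWindow",
    "CpGIsland",
    "gc_fraction",
    "cpg_obs_exp",
    "qualifying_window_starts",
    "find_cgis",
    "promoter_windows",
    "promoter_cgis",
    "to_one_based",
    "from_one_based",
    "write_islands",
]


@dataclass(frozen=True)
class CgiParams:
    window_len: int = 200
    gc_min: float = 0.50
    oe_min: float = 0.60
    min_island_len: int = 200
    upstream: int = 1500
    downstream: int = 1000

    def __post_init__(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream/downstream must be >= 0")


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open
    end: int


@dataclass(frozen=True)
class CpGIsland:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gc: float
    oe: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_window(seq: str) -> None:
    if not seq:
        raise ValueError("empty window")
    if any(b not in "ACGT" for b in seq):
        raise ValueError("window must contain uppercase A/C/G/T only")


def gc_fraction(window: str) -> float:
    """G+C fraction of an uppercase, unmasked window."""
    _check_window(window)
    return (window.count("G") + window.count("C")) / len(window)


def cpg_obs_exp(window: str) -> float:
    """Observed/expected CpG ratio; 0 when the window has no C or no G."""
    _check_window(window)
    n_c = window.count("C")
    n_g = window.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = window.count("CG")
    return n_cg * len(window) / (n_c * n_g)


def _base_arrays(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Boolean indicator arrays (isC, isG, isCpG-start, valid) over a sequence."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    valid = is_c | is_g | (arr == ord("A")) | (arr == ord("T"))
    cg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        cg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, cg, valid


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return cs[w:] - cs[:-w]


def qualifying_window_starts(sequence: str, params: CgiParams = CgiParams()) -> np.ndarray:
    """Start positions of windows passing the GC / O/E / unmasked criteria.

    Window-level qualification is monotone in the thresholds: raising
    ``gc_min`` or ``oe_min`` can only shrink this set.
    """
    w = params.window_len
    n = len(sequence)
    if n < w:
        return np.empty(0, dtype=np.int64)
    is_c, is_g, cg, valid = _base_arrays(sequence)
    n_windows = n - w + 1
    c_w = _window_sums(is_c, w)
    g_w = _window_sums(is_g, w)
    bad_w = _window_sums(~valid, w)
    # a CpG counts for window start i when the C lies in [i, i+w-1)
    cg_w = _window_sums(cg[:-1], w - 1) if w > 1 else np.zeros(n_windows, dtype=np.int64)

    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((c_w > 0) & (g_w > 0), cg_w * w / np.maximum(c_w * g_w, 1), 0.0)
    gc = (c_w + g_w) / w
    qualifies = (bad_w == 0) & (gc >= params.gc_min) & (oe >= params.oe_min)
    return np.flatnonzero(qualifies)


def find_cgis(sequence: str, params: CgiParams = CgiParams(), chrom: str = "") -> list[CpGIsland]:
    """Call CpG islands on one sequence with rolling window counts.

    Runs in O(len(sequence)); masked (lowercase) and N bases disqualify
    every window that contains them. Islands are maximal runs of
    positions covered by qualifying windows whose whole-span statistics
    still pass both thresholds.
    """
    w = params.window_len
    n = len(sequence)
    starts = qualifying_window_starts(sequence, params)
    if len(starts) == 0:
        return []
    # union of qualifying windows via a difference array over positions
    cover = np.zeros(n + 1, dtype=np.int32)
    np.add.at(cover, starts, 1)
    np.add.at(cover, starts + w, -1)
    covered = np.cumsum(cover[:-1]) > 0

    islands: list[CpGIsland] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        span = sequence[s:e]
        if e - s < params.min_island_len:
            continue
        gc_span = gc_fraction(span)
        oe_span = cpg_obs_exp(span)
        if gc_span >= params.gc_min and oe_span >= params.oe_min:
            islands.append(CpGIsland(chrom=chrom, start=int(s), end=int(e), gc=gc_span, oe=oe_span))
    return islands


def promoter_windows(annotation: GenomeAnnotation, params: CgiParams = CgiParams()) -> list[PromoterWindow]:
    """Strand-aware promoter windows around each gene's TSS.

    Plus strand: [tss - upstream, tss + downstream); minus strand is the
    mirror image so that ``upstream`` bases lie transcriptionally
    upstream. Windows are clipped to chromosome bounds and identical
    duplicate windows per gene are collapsed.
    """
    seen: set[tuple[str, str, int, int]] = set()
    out: list[PromoterWindow] = []
    for g in annotation.genes:
        if g.chrom not in annotation.sequences:
            raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
        clen = annotation.chrom_length(g.chrom)
        if g.strand == "+":
            start, end = g.tss - params.upstream, g.tss + params.downstream
        else:
            start, end = g.tss - params.downstream + 1, g.tss + params.upstream + 1
        start, end = max(0, start), min(clen, end)
        key = (g.gene_id, g.chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        out.append(PromoterWindow(gene_id=g.gene_id, chrom=g.chrom, strand=g.strand, start=start, end=end))
    return out


def promoter_cgis(
    annotation: GenomeAnnotation, params: CgiParams = CgiParams()
) -> dict[str, list[CpGIsland]]:
    """CpG islands called within each gene's promoter window.

    Islands are reported in genomic coordinates; an island overlapping
    two genes' windows appears under both genes.
    """
    result: dict[str, list[CpGIsland]] = {}
    for win in promoter_windows(annotation, params):
        sub = annotation.sequences[win.chrom][win.start : win.end]
        found = find_cgis(sub, params, chrom=win.chrom)
        shifted = [
            CpGIsland(chrom=win.chrom, start=i.start + win.start, end=i.end + win.start, gc=i.gc, oe=i.oe)
            for i in found
        ]
        result.setdefault(win.gene_id, []).extend(shifted)
    # collapse duplicates per gene (several transcripts -> same window)
    for gid, islands in result.items():
        uniq = {(i.chrom, i.start, i.end): i for i in islands}
        result[gid] = sorted(uniq.values(), key=lambda i: (i.chrom, i.start))
    return result


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (reporting convention)."""
    return start + 1, end


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def write_islands(per_gene: dict[str, list[CpGIsland]], out_dir: str | Path) -> None:
    """Write BED6 + TSV island tables under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed_rows = []
    tsv_rows = []
    for gid in sorted(per_gene):
        for k, isl in enumerate(per_gene[gid]):
            name = f"{gid}:{k}"
            bed_rows.append((isl.chrom, isl.start, isl.end, name, round(1000 * isl.oe), "."))
            tsv_rows.append(
                {"gene_id": gid, "island_id": name, "chrom": isl.chrom, "start": isl.start,
                 "end": isl.end, "length": isl.length, "gc": isl.gc, "oe": isl.oe}
            )
    write_bed6(bed_rows, out_dir / "islands.bed")
    pd.DataFrame(
        tsv_rows, columns=["gene_id", "island_id", "chrom", "start", "end", "length", "gc", "oe"]
    ).to_csv(out_dir / "islands.tsv", sep="\t", index=False)
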