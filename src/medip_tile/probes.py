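"""Tiling-array probe design over CpG islands.

60-mer probes are laid down every 25 bp across each island; when the
stepped grid stops short of the island end, one extra probe is
right-anchored so the union of probes covers the island exactly
("covering the entire region"). Probes failing genome-wide uniqueness at
55-bp resolution are removed: a probe is dropped when any of its 55-mers
occurs at more than one genomic location, counting both strands.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cgi import CpGIsland
from .genome import write_bed6

__all__ = [
    "ProbeParams",
    "Probe",
    "ArrayDesign",
    "tile_probes",
    "tile_all",
    "specificity_filter",
    "build_design",
    "write_manifest",
    "read_manifest",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProbeParams:
    probe_len: int = 60
    step: int = 25
    uniq_len: int = 55
    n_control_features: int = 0
    n_blank_features: int = 0

    def __post_init__(self) -> None:
        if self.uniq_len > self.probe_len:
            raise ValueError("uniq_len must be <= probe_len")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class Probe:
    probe_id: str
    chrom: str
    start: int  # 0-based half-open, end - start == probe_len
    end: int
    sequence: str
    island_ref: str
    gene_ids: tuple[str, ...] = ()


@dataclass
class ArrayDesign:
    probes: list[Probe]
    n_control_features: int = 0
    n_blank_features: int = 0

    @property
    def total_features(self) -> int:
        return len(self.probes) + self.n_control_features + self.n_blank_features


def tile_probes(
    island: CpGIsland,
    genome: dict[str, str],
    params: ProbeParams = ProbeParams(),
    island_id: str = "",
    gene_ids: tuple[str, ...] = (),
) -> list[Probe]:
    """Tile probes across one island with full coverage.

    Islands shorter than ``probe_len`` get a single centered probe
    extended into unmasked flanks when available, otherwise the island is
    skipped with a logged reason.
    """
    seq = genome[island.chrom]
    if island.start < 0 or island.end > len(seq):
        raise ValueError(f"island {island_id or island} outside chromosome {island.chrom}")
    L = island.length
    plen = params.probe_len
    island_id = island_id or f"{island.chrom}:{island.start}-{island.end}"

    def make(start: int, idx: int) -> Probe:
        sub = seq[start : start + plen]
        return Probe(
            probe_id=f"{island_id}_p{idx:03d}",
            chrom=island.chrom,
            start=start,
            end=start + plen,
            sequence=sub.upper(),
            island_ref=island_id,
            gene_ids=gene_ids,
        )

    if L < plen:
        # center on the island, borrowing flank sequence
        start = island.start - (plen - L) // 2
        start = max(0, min(start, len(seq) - plen))
        if start > island.start or start + plen < island.end or len(seq) < plen:
            logger.warning("island %s skipped: insufficient flank for a %d-mer", island_id, plen)
            return []
        flank = seq[start : island.start] + seq[island.end : start + plen]
        if any(b.islower() or b == "N" for b in flank):
            logger.warning("island %s skipped: masked flank", island_id)
            return []
        return [make(start, 0)]

    starts = list(range(island.start, island.end - plen + 1, params.step))
    if starts[-1] + plen < island.end:
        starts.append(island.end - plen)  # right-anchored terminal probe
    return [make(s, k) for k, s in enumerate(starts)]


def tile_all(
    per_gene_islands: dict[str, list[CpGIsland]],
    genome: dict[str, str],
    params: ProbeParams = ProbeParams(),
) -> list[Probe]:
    """Tile every island; islands shared between genes are tiled once
    with all gene ids attached."""
    by_coord: dict[tuple[str, int, int], tuple[CpGIsland, list[str]]] = {}
    for gid in sorted(per_gene_islands):
        for isl in per_gene_islands[gid]:
            key = (isl.chrom, isl.start, isl.end)
            by_coord.setdefault(key, (isl, []))[1].append(gid)
    probes: list[Probe] = []
    for k, ((chrom, start, end), (isl, gids)) in enumerate(sorted(by_coord.items())):
        island_id = f"CGI{k:05d}_{chrom}:{start}-{end}"
        probes.extend(tile_probes(isl, genome, params, island_id=island_id, gene_ids=tuple(gids)))
    return probes


def _kmer_counts(genome: dict[str, str], k: int) -> Counter:
    """Occurrence count of every canonical k-mer over both strands.

    A k-mer and its reverse complement are one key; palindromic k-mers
    are counted once per locus. Masked (lowercase) loci still count —
    uniqueness is a property of the genome, not of the mask.
    """
    counts: Counter = Counter()
    for seq in genome.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            counts[min(kmer, rc)] += 1
    return counts


def specificity_filter(
    probes: list[Probe],
    genome: dict[str, str],
    params: ProbeParams = ProbeParams(),
) -> tuple[list[Probe], list[tuple[Probe, str]]]:
    """Remove probes that are not genome-unique at ``uniq_len`` resolution.

    A probe is removed iff any of its ``probe_len - uniq_len + 1``
    substrings of length ``uniq_len`` occurs at more than one genomic
    location (both strands counted; the probe's own locus counts once).
    """
    k = params.uniq_len
    counts = _kmer_counts(genome, k)
    kept: list[Probe] = []
    removed: list[tuple[Probe, str]] = []
    for p in probes:
        seq = p.sequence.upper()
        offending = None
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if counts[min(kmer, revcomp(kmer))] > 1:
                offending = kmer
                break
        if offending is None:
            kept.append(p)
        else:
            removed.append((p, f"non-unique {k}-mer at probe offset {seq.find(offending)}"))
    return kept, removed


def build_design(
    kept_probes: list[Probe],
    params: ProbeParams = ProbeParams(),
) -> ArrayDesign:
    """Assemble the final array design with feature accounting."""
    ids = [p.probe_id for p in kept_probes]
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate probe id {dup!r}")
    return ArrayDesign(
        probes=list(kept_probes),
        n_control_features=params.n_control_features,
        n_blank_features=params.n_blank_features,
    )


_MANIFEST_COLS = ["probe_id", "chrom", "start", "end", "strand", "sequence", "island_id", "gene_ids", "status"]


def write_manifest(design: ArrayDesign, path: str | Path, removed: list[tuple[Probe, str]] = ()) -> None:
    rows = [
        {
            "probe_id": p.probe_id, "chrom": p.chrom, "start": p.start, "end": p.end,
            "strand": "+", "sequence": p.sequence, "island_id": p.island_ref,
            "gene_ids": ",".join(p.gene_ids), "status": "kept",
        }
        for p in design.probes
    ]
    for p, reason in removed:
        rows.append(
            {
                "probe_id": p.probe_id, "chrom": p.chrom, "start": p.start, "end": p.end,
                "strand": "+", "sequence": p.sequence, "island_id": p.island_ref,
                "gene_ids": ",".join(p.gene_ids), "status": f"removed:{reason}",
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# probes={len(design.probes)}\n")
        fh.write(f"# control_features={design.n_control_features}\n")
        fh.write(f"# blank_features={design.n_blank_features}\n")
        fh.write(f"# total_features={design.total_features}\n")
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, sep="\t", index=False, mode="a")


def read_manifest(path: str | Path) -> ArrayDesign:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = int(val)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_ids": str}, keep_default_na=False)
    probes = [
        Probe(
            probe_id=r.probe_id, chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            sequence=r.sequence, island_ref=r.island_id,
            gene_ids=tuple(g for g in str(r.gene_ids).split(",") if g),
        )
        for r in df.itertuples()
        if r.status == "kept"
    ]
    design = ArrayDesign(
        probes=probes,
        n_control_features=meta.get("control_features", 0),
        n_blank_features=meta.get("blank_features", 0),
    )
    if "total_features" in meta and design.total_features != meta["total_features"]:
        raise ValueError("manifest feature accounting mismatch")
    return design


def write_probe_bed(design: ArrayDesign, path: str | Path) -> None:
    write_bed6(((p.chrom, p.start, p.end, p.probe_id, 0, "+") for p in design.probes), path)
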