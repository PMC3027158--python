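"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's rolling-count /
hash-based implementations: CGI calling is re-derived by testing every
window position one at a time with plain string ops, and probe
uniqueness by counting substring occurrences with ``str`` scans.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from medip_tile.cgi import CgiParams, CpGIsland
from medip_tile.probes import revcomp

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Brute-force CGI oracle

def brute_force_cgis(sequence: str, params: CgiParams = CgiParams()) -> list[tuple[int, int]]:
    """Island coordinates from per-window brute force (no rolling counts)."""
    w = params.window_len
    n = len(sequence)
    covered = [False] * n
    for i in range(n - w + 1):
        win = sequence[i : i + w]
        if not set(win) <= set("ACGT"):
            continue
        gc = (win.count("G") + win.count("C")) / w
        n_c, n_g = win.count("C"), win.count("G")
        oe = win.count("CG") * w / (n_c * n_g) if n_c and n_g else 0.0
        if gc >= params.gc_min and oe >= params.oe_min:
            for j in range(i, i + w):
                covered[j] = True
    islands = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and covered[j]:
                j += 1
            span = sequence[i:j]
            if j - i >= params.min_island_len:
                gc = (span.count("G") + span.count("C")) / len(span)
                n_c, n_g = span.count("C"), span.count("G")
                oe = span.count("CG") * len(span) / (n_c * n_g) if n_c and n_g else 0.0
                if gc >= params.gc_min and oe >= params.oe_min:
                    islands.append((i, j))
            i = j
        else:
            i += 1
    return islands


# ---------------------------------------------------------------------------
# Brute-force k-mer occurrence oracle

def count_occurrences(haystack: str, needle: str) -> int:
    """Overlap-aware substring count."""
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def brute_force_unique(probe_seq: str, genome: dict[str, str], k: int) -> bool:
    """True iff every k-mer of the probe occurs at exactly one genomic
    locus, counting both strands by scanning plain strings."""
    seqs = [s.upper() for s in genome.values()]
    for i in range(len(probe_seq) - k + 1):
        kmer = probe_seq[i : i + k].upper()
        rc = revcomp(kmer)
        hits = sum(count_occurrences(s, kmer) for s in seqs)
        if rc != kmer:
            hits += sum(count_occurrences(s, rc) for s in seqs)
        if hits > 1:
            return False
    return True


# ---------------------------------------------------------------------------
# Random test sequences

def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def planted_test_sequence(rng: np.random.Generator, length: int) -> str:
    """Background with 0-2 CpG-rich tracts, plus masked/N tracts."""
    from medip_tile.synthetic import markov_sequence

    seq = list(markov_sequence(rng, length, 0.40, 0.20))
    for _ in range(int(rng.integers(0, 3))):
        tract_len = int(rng.integers(120, 500))
        start = int(rng.integers(0, max(1, length - tract_len)))
        tract = markov_sequence(rng, tract_len, 0.62, 0.90)
        seq[start : start + tract_len] = list(tract)
    for _ in range(int(rng.integers(0, 3))):  # soft-masked tract
        tract_len = int(rng.integers(50, 300))
        start = int(rng.integers(0, max(1, length - tract_len)))
        seq[start : start + tract_len] = [b.lower() for b in seq[start : start + tract_len]]
    if rng.random() < 0.5:  # N tract
        tract_len = int(rng.integers(10, 60))
        start = int(rng.integers(0, max(1, length - tract_len)))
        seq[start : start + tract_len] = ["N"] * tract_len
    return "".join(seq)


@pytest.fixture(scope="session")
def small_genome():
    """A small deterministic genome with planted promoter islands."""
    from medip_tile.synthetic import GenomeConfig, make_genome

    config = GenomeConfig(n_chromosomes=2, chrom_length=60_000, n_genes=8, seed=11)
    annotation, truth = make_genome(config)
    return config, annotation, truth


@pytest.fixture()
def dummy_island():
    def make(chrom: str, start: int, end: int) -> CpGIsland:
        return CpGIsland(chrom=chrom, start=start, end=end, gc=0.6, oe=0.8)

    return make
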