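"""Synthetic genomes, methylation truth, array channels, traces, HPLC.

Every downstream stage of the pipeline is testable without external
downloads: this module emulates a CpG-depleted genome with promoter CpG
islands planted inside strand-aware promoter windows, a bimodal
per-region methylation landscape (most islands unmethylated, a small
minority fully methylated), tumor-specific hypo/hyper effects applied on
the odds (logit) scale, a two-channel signal model with multiplicative
probe affinity and measurement noise, direct bisulfite sequencing
traces, and HPLC mononucleotide profiles.

All randomness flows through :func:`stream`, which derives one
independent RNG per (seed, operation-name) pair, so stages are decoupled
and identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bsp import BisulfiteTrace, HplcProfile, Site
from .cgi import CgiParams, CpGIsland, find_cgis
from .genome import Gene, GenomeAnnotation, write_bed6, write_fasta, write_gff3
from .probes import ArrayDesign, Probe

__all__ = [
    "GenomeConfig",
    "TruthIsland",
    "MethylationParams",
    "MethylationTruth",
    "SignalModel",
    "stream",
    "markov_sequence",
    "make_genome",
    "make_methylation",
    "simulate_array",
    "simulate_traces",
    "simulate_hplc",
    "simulate_bsp_screen",
    "flat_design",
    "flat_truth_islands",
    "default_groups",
    "write_genome_files",
]

_BASES = np.array(list("ACGT"))


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream for one operation under one global seed."""
    salt = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, salt]))


# ---------------------------------------------------------------------------
# Sequence generation

def markov_sequence(rng: np.random.Generator, length: int, gc: float, cpg_oe: float) -> str:
    """First-order Markov sequence with target GC and CpG observed/expected.

    Stationary base probabilities put ``gc`` mass on G+C (split evenly);
    the transition row out of C rescales P(G|C) to ``cpg_oe * pi_G`` and
    redistributes the deficit over A/C/T, which depletes (or enriches)
    CpG dinucleotides to roughly the requested O/E. Realized GC is
    therefore approximate, not exact.
    """
    if length <= 0:
        return ""
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    row_c = pi.copy()
    row_c[2] = cpg_oe * pi[2]
    rest = 1.0 - row_c[2]
    others = pi.copy()
    others[2] = 0.0
    row_c[[0, 1, 3]] = pi[[0, 1, 3]] / others.sum() * rest
    # common row for A/G/T chosen so that pi stays the exact stationary
    # distribution: pi = pi_C * row_c + (1 - pi_C) * row_other
    row_other = np.clip((pi - pi[1] * row_c) / (1 - pi[1]), 0.0, None)
    row_other /= row_other.sum()
    cum_default = np.cumsum(row_other)
    cum_c = np.cumsum(row_c)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    prev = int(np.searchsorted(np.cumsum(pi), u[0]))
    out[0] = prev
    for i in range(1, length):
        cum = cum_c if prev == 1 else cum_default
        prev = int(np.searchsorted(cum, u[i]))
        out[i] = prev
    return "".join(_BASES[out])


# ---------------------------------------------------------------------------
# Genome + truth islands

@dataclass(frozen=True)
class GenomeConfig:
    n_chromosomes: int = 2
    chrom_length: int = 150_000
    n_genes: int = 20
    background_gc: float = 0.40
    background_cpg_oe: float = 0.20
    island_gc_range: tuple[float, float] = (0.55, 0.65)
    island_oe_range: tuple[float, float] = (0.75, 0.95)
    island_len_range: tuple[int, int] = (250, 500)
    repeat_fraction: float = 0.10
    seed: int = 0
    plant_islands: bool = True
    cgi_params: CgiParams = field(default_factory=CgiParams)

    def __post_init__(self) -> None:
        for name in ("background_gc", "background_cpg_oe", "repeat_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("island_gc_range", "island_oe_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1.5):
                raise ValueError(f"{name} must be an ordered pair of fractions")
        if self.plant_islands and self.island_len_range[0] < self.cgi_params.min_island_len:
            raise ValueError(
                "island_len_range lower bound must be >= the CGI minimum island length "
                f"({self.cgi_params.min_island_len})"
            )


@dataclass(frozen=True)
class TruthIsland:
    island_id: str
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int


def _verified_island_sequence(
    rng: np.random.Generator, length: int, gc: float, oe: float, params: CgiParams
) -> str:
    """Draw an island sequence until the caller's CGI thresholds accept it
    as a single island spanning the whole sequence (bounded retries)."""
    for _ in range(100):
        seq = markov_sequence(rng, length, gc, oe)
        called = find_cgis(seq, params)
        if len(called) == 1 and called[0].start == 0 and called[0].end == length:
            return seq
    raise RuntimeError(
        f"could not realize a CGI of length {length} at GC={gc:.2f}, O/E={oe:.2f} "
        "that passes the configured thresholds"
    )


def make_genome(config: GenomeConfig) -> tuple[GenomeAnnotation, list[TruthIsland]]:
    """Generate a soft-masked genome with one planted promoter CGI per gene.

    Genes are spread over evenly sized slots per chromosome; each gene's
    promoter window (strand-aware, upstream/downstream from
    ``config.cgi_params``) receives one island drawn from the configured
    GC / O/E / length ranges, pre-verified to pass the CGI thresholds.
    ``repeat_fraction`` of the background (never the promoter windows)
    is lowercased. Same config => byte-identical output.
    """
    p = config.cgi_params
    win_len = p.upstream + p.downstream
    rng = stream(config.seed, "make_genome")

    # distribute genes over chromosomes
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    max_island = config.island_len_range[1] if config.plant_islands else 0
    needed = win_len + 100
    for k in per_chrom:
        if k and config.chrom_length // k < needed:
            raise ValueError(
                f"chrom_length {config.chrom_length} cannot pack {k} non-overlapping "
                f"promoter windows of {win_len} bp (need >= {k * needed})"
            )
    if max_island > win_len:
        raise ValueError("island_len_range upper bound exceeds the promoter window")

    sequences: dict[str, str] = {}
    genes: list[Gene] = []
    truth: list[TruthIsland] = []
    gene_idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        bg = markov_sequence(rng, config.chrom_length, config.background_gc, config.background_cpg_oe)
        seq = np.array(list(bg))
        n_here = per_chrom[c]
        windows: list[tuple[int, int]] = []
        for j in range(n_here):
            slot = config.chrom_length // n_here
            win_start = j * slot + (slot - win_len) // 2
            win_end = win_start + win_len
            windows.append((win_start, win_end))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss = win_start + p.upstream
                g_start, g_end = tss, min(tss + 800, config.chrom_length)
            else:
                tss = win_start + p.downstream - 1
                g_start, g_end = max(0, tss - 799), tss + 1
            gid = f"gene{gene_idx + 1:04d}"
            genes.append(Gene(gene_id=gid, chrom=chrom, strand=strand, tss=tss, start=g_start, end=g_end))
            if config.plant_islands:
                gc = rng.uniform(*config.island_gc_range)
                oe = rng.uniform(*config.island_oe_range)
                length = int(rng.integers(config.island_len_range[0], config.island_len_range[1] + 1))
                isl_start = int(rng.integers(win_start, win_end - length + 1))
                # redraw until the island, in its genomic context, is called
                # as one CGI containing the planted span (coverage can leak
                # into flanks, and the whole-span recheck must still pass)
                for _ in range(50):
                    isl_seq = _verified_island_sequence(rng, length, gc, oe, p)
                    seq[isl_start : isl_start + length] = list(isl_seq)
                    sub = "".join(seq[win_start:win_end])
                    called = find_cgis(sub, p)
                    rel = isl_start - win_start
                    if sum(1 for i in called if i.start <= rel and i.end >= rel + length) == 1:
                        break
                else:
                    raise RuntimeError(
                        f"could not plant a verifiable island for {gid} after 50 draws"
                    )
                truth.append(
                    TruthIsland(
                        island_id=f"{gid}_cgi", gene_id=gid, chrom=chrom,
                        start=isl_start, end=isl_start + length,
                    )
                )
            gene_idx += 1

        # soft-mask repeats outside promoter windows
        target = int(config.repeat_fraction * config.chrom_length)
        masked = 0
        attempts = 0
        while masked < target and attempts < 10_000:
            attempts += 1
            tract = int(rng.integers(100, 401))
            start = int(rng.integers(0, config.chrom_length - tract))
            if any(start < we and start + tract > ws for ws, we in windows):
                continue
            block = seq[start : start + tract]
            lower = np.char.lower(block)
            masked += int(np.sum(block != lower))
            seq[start : start + tract] = lower
        sequences[chrom] = "".join(seq)

    return GenomeAnnotation(sequences=sequences, genes=genes), truth


def write_genome_files(
    annotation: GenomeAnnotation, truth: list[TruthIsland], out_dir: str | Path
) -> None:
    """FASTA (60-col), GFF3 and a BED6 truth-island track under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(annotation.sequences, out_dir / "genome.fa")
    write_gff3(annotation, out_dir / "genes.gff3")
    write_bed6(
        ((t.chrom, t.start, t.end, t.island_id, 0, ".") for t in truth),
        out_dir / "truth_islands.bed",
    )


# ---------------------------------------------------------------------------
# Methylation truth

@dataclass(frozen=True)
class MethylationParams:
    baseline_high_prob: float = 1 / 14  # cf. 1 methylated of 14 screened genes
    baseline_low: float = 0.05
    baseline_high: float = 0.90
    n_hypo: int = 0
    n_hyper: int = 0
    effect_fold: float = 2.5
    replicate_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_fold <= 1 and (self.n_hypo or self.n_hyper):
            raise ValueError("effect_fold must be > 1")
        if not 0 <= self.baseline_high_prob <= 1:
            raise ValueError("baseline_high_prob must be in [0, 1]")


@dataclass
class MethylationTruth:
    """Per-region per-sample methylation fractions plus the effect ledger."""

    m: pd.DataFrame  # index region_id, columns sample_id, values in [0, 1]
    groups: pd.Series  # sample_id -> group
    effects: pd.DataFrame  # columns: region_id, direction, effect_fold

    def regions(self, direction: str) -> list[str]:
        return self.effects.loc[self.effects["direction"] == direction, "region_id"].tolist()


def _odds_shift(m: np.ndarray, fold: float, direction: str) -> np.ndarray:
    """Shift methylation fractions by ``fold`` on the odds scale."""
    if direction == "hypo":
        return m / (m + fold * (1 - m))
    return fold * m / (fold * m + (1 - m))


def make_methylation(
    truth_islands: list[TruthIsland],
    groups: dict[str, str] | pd.Series,
    params: MethylationParams = MethylationParams(),
    hypo_regions: list[str] | None = None,
    hyper_regions: list[str] | None = None,
) -> MethylationTruth:
    """Draw the bimodal methylation landscape and plant tumor effects.

    Baseline fractions are a two-component mixture (low around 0.05,
    high around 0.9). Tumor samples have ``n_hypo`` regions shifted down
    and ``n_hyper`` shifted up by ``effect_fold`` on the odds scale;
    replicate jitter (sd ``replicate_sd``) is added per biological
    sample and clipped to [0, 1]. The positive-control sample is 1
    everywhere, the negative-control 0 everywhere.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    region_ids = [t.island_id for t in truth_islands]
    if len(set(region_ids)) != len(region_ids):
        raise ValueError("duplicate island ids")
    rng = stream(params.seed, "make_methylation")

    n = len(region_ids)
    baseline = np.where(
        rng.random(n) < params.baseline_high_prob, params.baseline_high, params.baseline_low
    )
    base = pd.Series(baseline, index=region_ids)

    if hypo_regions is not None or hyper_regions is not None:
        hypo = list(hypo_regions or [])
        hyper = list(hyper_regions or [])
        unknown = (set(hypo) | set(hyper)) - set(region_ids)
        if unknown:
            raise ValueError(f"effect regions not in truth: {sorted(unknown)}")
    else:
        # Differential events are planted on the unmethylated-majority
        # component: constitutively methylated islands (the high-baseline
        # minority, ntla-like) are stable between tumor and control.
        eligible = [r for r in region_ids if base[r] < 0.5]
        if params.n_hypo + params.n_hyper > len(eligible):
            raise ValueError("n_hypo + n_hyper exceeds the number of low-baseline islands")
        chosen = rng.choice(len(eligible), size=params.n_hypo + params.n_hyper, replace=False)
        hypo = [eligible[i] for i in chosen[: params.n_hypo]]
        hyper = [eligible[i] for i in chosen[params.n_hypo :]]
    if set(hypo) & set(hyper):
        raise ValueError(f"hypo and hyper sets overlap: {sorted(set(hypo) & set(hyper))}")
    tumor_base = base.copy()
    if hypo:
        tumor_base[hypo] = _odds_shift(base[hypo].to_numpy(), params.effect_fold, "hypo")
    if hyper:
        tumor_base[hyper] = _odds_shift(base[hyper].to_numpy(), params.effect_fold, "hyper")

    cols = {}
    for sample in groups.index:
        grp = groups[sample]
        if grp == "positive":
            cols[sample] = np.ones(n)
        elif grp == "negative":
            cols[sample] = np.zeros(n)
        else:
            center = tumor_base if grp == "tumor" else base
            jitter = rng.normal(0.0, params.replicate_sd, size=n)
            cols[sample] = np.clip(center.to_numpy() + jitter, 0.0, 1.0)
    m = pd.DataFrame(cols, index=region_ids)

    effects = pd.DataFrame(
        [{"region_id": r, "direction": "hypo", "effect_fold": params.effect_fold} for r in hypo]
        + [{"region_id": r, "direction": "hyper", "effect_fold": params.effect_fold} for r in hyper],
        columns=["region_id", "direction", "effect_fold"],
    )
    return MethylationTruth(m=m, groups=groups.copy(), effects=effects)


# ---------------------------------------------------------------------------
# Array signal model

@dataclass(frozen=True)
class SignalModel:
    """Affine-in-methylation two-channel signal model.

    Cy5 = B_p * (alpha + beta * m) * eps, Cy3 = B_p * eps', with a
    per-probe lognormal affinity B_p shared across samples and
    mean-one lognormal multiplicative noise of coefficient of variation
    ``noise_cv`` per channel. The present flag is Cy5 above
    ``detection_threshold``.
    """

    alpha_nonspecific: float = 5.0
    beta_enrichment: float = 995.0
    affinity_sigma: float = 0.30
    noise_cv: float = 0.10
    detection_threshold: float = 25.0

    def __post_init__(self) -> None:
        if self.alpha_nonspecific <= 0:
            raise ValueError("alpha_nonspecific must be > 0")
        if self.beta_enrichment <= 0:
            raise ValueError("beta_enrichment must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=shape)


def simulate_array(
    design: ArrayDesign,
    truth: MethylationTruth,
    model: SignalModel = SignalModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-channel hybridization for every sample in the truth.

    Returns a long-format channel table with columns
    ``sample_id, group, probe_id, cy3, cy5, present``.
    """
    rng = stream(seed, "simulate_array")
    probe_regions = [p.island_ref for p in design.probes]
    missing = set(probe_regions) - set(truth.m.index)
    if missing:
        raise ValueError(f"probes map to unknown regions: {sorted(missing)[:5]}")
    m = truth.m.loc[probe_regions].to_numpy(float)  # probes x samples
    n_probes, n_samples = m.shape
    if model.affinity_sigma > 0:
        affinity = rng.lognormal(mean=0.0, sigma=model.affinity_sigma, size=n_probes)
    else:
        affinity = np.ones(n_probes)
    eps5 = _lognormal_noise(rng, model.noise_cv, (n_probes, n_samples))
    eps3 = _lognormal_noise(rng, model.noise_cv, (n_probes, n_samples))
    cy5 = affinity[:, None] * (model.alpha_nonspecific + model.beta_enrichment * m) * eps5
    cy3 = affinity[:, None] * eps3
    present = cy5 > model.detection_threshold

    samples = list(truth.m.columns)
    probe_ids = [p.probe_id for p in design.probes]
    frames = []
    for j, s in enumerate(samples):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s,
                    "group": truth.groups[s],
                    "probe_id": probe_ids,
                    "cy3": cy3[:, j],
                    "cy5": cy5[:, j],
                    "present": present[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def flat_design(n_probes: int, chrom: str = "sim") -> ArrayDesign:
    """One probe per synthetic region; handy for pure signal simulations."""
    probes = [
        Probe(
            probe_id=f"R{i:05d}_p000", chrom=chrom, start=i * 100, end=i * 100 + 60,
            sequence="", island_ref=f"R{i:05d}", gene_ids=(f"G{i:05d}",),
        )
        for i in range(n_probes)
    ]
    return ArrayDesign(probes=probes)


def flat_truth_islands(n: int, chrom: str = "sim") -> list[TruthIsland]:
    return [
        TruthIsland(island_id=f"R{i:05d}", gene_id=f"G{i:05d}", chrom=chrom,
                    start=i * 100, end=i * 100 + 60)
        for i in range(n)
    ]


def default_groups(n_tumor: int = 4, n_control: int = 4, n_positive: int = 1, n_negative: int = 1) -> dict[str, str]:
    """The study layout: biological tumor/control replicates plus the
    artificially methylated (positive) and amplified (negative) samples."""
    groups: dict[str, str] = {}
    groups.update({f"C{i+1}": "control" for i in range(n_control)})
    groups.update({f"T{i+1}": "tumor" for i in range(n_tumor)})
    groups.update({f"POS{i+1}" if n_positive > 1 else "POS": "positive" for i in range(n_positive)})
    groups.update({f"NEG{i+1}" if n_negative > 1 else "NEG": "negative" for i in range(n_negative)})
    return groups


# ---------------------------------------------------------------------------
# Bisulfite traces

def simulate_traces(
    island_sequence: str,
    m: float,
    noise_sd: float = 0.05,
    conversion_rate: float = 1.0,
    seed: int = 0,
    region_id: str = "region",
    sample_id: str = "sample",
    group: str = "control",
) -> BisulfiteTrace:
    """Simulate direct-sequencing C/T peak areas for one region.

    CpG-site C areas are proportional to the methylation fraction ``m``
    (T areas to 1 - m); non-CpG cytosines read as T in proportion to the
    bisulfite ``conversion_rate``. Gaussian noise of sd ``noise_sd`` is
    added to every peak and areas are clipped at zero.
    """
    if not 0 <= m <= 1:
        raise ValueError("m must be in [0, 1]")
    if not 0 < conversion_rate <= 1:
        raise ValueError("conversion_rate must be in (0, 1]")
    seq = island_sequence.upper()
    cpg_pos = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    if not cpg_pos:
        raise ValueError("island sequence contains no CpG site")
    non_cpg_pos = [
        i for i in range(len(seq)) if seq[i] == "C" and (i + 1 >= len(seq) or seq[i + 1] != "G")
    ]
    rng = stream(seed, "simulate_traces")

    def peak(center: float) -> float:
        return float(max(0.0, center + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)))

    cpg_sites = [Site(i, peak(m), peak(1 - m)) for i in cpg_pos]
    non_cpg = [Site(i, peak(1 - conversion_rate), peak(conversion_rate)) for i in non_cpg_pos]
    return BisulfiteTrace(
        region_id=region_id, sample_id=sample_id, group=group,
        cpg_sites=cpg_sites, non_cpg_sites=non_cpg,
    )


def simulate_bsp_screen(
    n_genes: int = 14,
    n_regions: int = 15,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[list[BisulfiteTrace], dict[str, str], dict[str, float]]:
    """Simulate the MeDIP optimization screen: ``n_regions`` promoter
    regions across ``n_genes`` genes, exactly one fully methylated
    (ntla-like) and the rest fully unmethylated (gstp1-like).

    Returns (traces, region -> gene map, region -> true methylation).
    """
    if n_regions < n_genes:
        raise ValueError("need at least one region per gene")
    rng = stream(seed, "simulate_bsp_screen")
    region_gene: dict[str, str] = {}
    extra = n_regions - n_genes
    r = 0
    for g in range(n_genes):
        n_here = 1 + (1 if g < extra else 0)
        for _ in range(n_here):
            region_gene[f"region{r + 1:02d}"] = f"gene{g + 1:02d}"
            r += 1
    regions = sorted(region_gene)
    methylated_region = regions[-1]  # a single-region gene
    truth = {rid: (1.0 if rid == methylated_region else 0.0) for rid in regions}
    traces = []
    for rid in regions:
        seq = markov_sequence(rng, 300, 0.60, 0.85)
        if "CG" not in seq:  # vanishingly unlikely at this O/E, but be safe
            seq = seq[:150] + "CG" + seq[152:]
        traces.append(
            simulate_traces(
                seq, truth[rid], noise_sd=noise_sd, conversion_rate=1.0,
                seed=int(stream(seed, rid).integers(2**31)),
                region_id=rid, sample_id="S1", group="control",
            )
        )
    return traces, region_gene, truth


# ---------------------------------------------------------------------------
# HPLC

def simulate_hplc(
    percent_5mc: float,
    total_area: float = 100.0,
    noise_sd: float = 0.0,
    rna_contamination: bool = False,
    seed: int = 0,
    cytosine_fraction: float = 0.2,
) -> HplcProfile:
    """Simulate a mononucleotide HPLC profile at a given global 5mC level.

    Noise-free, dC and 5mdC sum to the cytosine share of ``total_area``
    with 5mdC/(dC + 5mdC) = percent_5mc / 100. The uracil peak is zero
    unless ``rna_contamination`` is set.
    """
    if not 0 <= percent_5mc <= 100:
        raise ValueError("percent_5mc must be in [0, 100]")
    rng = stream(seed, "simulate_hplc")
    cyt = cytosine_fraction * total_area
    mdc = cyt * percent_5mc / 100.0
    dc = cyt - mdc
    dg = cytosine_fraction * total_area
    da = dt = (1 - 2 * cytosine_fraction) * total_area / 2
    areas = {"dC": dc, "5mdC": mdc, "dG": dg, "dA": da, "dT": dt,
             "U": 0.05 * total_area if rna_contamination else 0.0}
    if noise_sd > 0:
        areas = {k: float(max(0.0, v + rng.normal(0.0, noise_sd))) for k, v in areas.items()}
    return HplcProfile(areas=areas)
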