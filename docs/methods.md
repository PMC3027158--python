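# Methods

This note documents the models, conventions and numerical choices
behind `medip_tile`, and what the simulation-based tests do and do not
demonstrate.

## CpG-island calling

Islands are called with the classic vertebrate criteria on a sliding
window of `window_len` = 200 bp: %GC ≥ `gc_min` = 0.50 and
observed/expected CpG ratio O/E = (N_CpG·L)/(N_C·N_G) ≥ `oe_min` = 0.60.
A position is *covered* when at least one qualifying window overlaps
it; an island is a maximal covered run whose **whole-span** statistics
still pass both thresholds and whose length reaches `min_island_len` =
200 bp. This covered-union definition (the one an island plot produces)
was chosen over merge-then-shrink variants because it is unambiguous
and directly checkable against a per-window brute-force oracle, which
the test suite does on random sequences with planted CpG-rich tracts,
soft-masked tracts and N runs.

Conventions and consequences:

- Windows containing soft-masked (lowercase) or N bases are
  disqualified outright; repeat masking is encoded as lowercase FASTA.
- Islands whose whole-span recheck fails are **dropped**, not trimmed.
  A consequence worth knowing: island lists are *not* monotone in the
  thresholds — a merged loose-threshold run can fail its whole-span
  recheck while the shorter strict-threshold core passes. What is
  monotone is window-level qualification (exposed as
  `qualifying_window_starts`), and that is the property the suite
  asserts.
- Internal coordinates are 0-based half-open; `to_one_based` /
  `from_one_based` convert to the 1-based inclusive convention used in
  published coordinate tables (a printed span such as
  33649014–33649398 has length 385).

Promoter windows span `upstream` = 1500 bp to `downstream` = 1000 bp
around each transcript 5′ end: `[t−1500, t+1000)` on the plus strand
and the mirror `[t−999, t+1501)` on the minus strand, clipped to
chromosome bounds. Identical windows from transcripts sharing a 5′ end
are collapsed. An island overlapping two genes' windows is reported
under both genes.

## Probe design

60-mer probes start at `island.start + 25k`; if the stepped grid stops
short of the island end one extra probe is right-anchored at
`end − 60`, so probe union ⊇ island for every island ≥ 60 bp. Shorter
islands get a single centered probe extended into unmasked flank
sequence when available, otherwise they are skipped with a logged
reason. Uniqueness is enforced by exact 55-mer occurrence counting over
both genome strands (canonical k-mers): a probe is removed iff any of
its six 55-mers occurs at more than one locus. This is deterministic
and strand-aware, unlike an alignment-based filter; near-identical
(54/55) matches are deliberately not chased. Counting ignores the
repeat mask — uniqueness is a property of the genome sequence, not of
its annotation.

## Two-channel analysis

Per probe and sample, the raw ratio is Cy5/Cy3 (entries with Cy3 ≤ 0
are invalid and excluded from presence counting). Each probe's ratios
are divided by that probe's mean over the **control biological
samples**, so control means are exactly 1 and fold changes read
directly as tumor/control; the artificial positive (fully methylated)
and negative (amplified, unmethylated) samples are excluded from the
reference and from testing but participate in presence counting and
PCA. An alternative per-array scalar normalization was considered and
rejected as it leaves fold changes probe-affinity-confounded.

Filters, applied in order with per-rule audit counts:

1. present flag in ≥ `present_min` = 4 of the samples (default layout:
   4 control + 4 tumor + 1 positive + 1 negative = 10);
2. mean raw Cy5 over biological samples ≥ `intensity_min` = 25
   (aggregate rather than per-sample — the per-sample variant is
   stricter than the workflow this emulates appears to have been);
3. SD of normalized ratios within each biological group ≤ `sd_max` =
   1.4 (evaluated on the linear ratio scale; failing either group
   removes the probe).

Differential calls use Welch's unequal-variance *t* on the linear
normalized ratios (a `log_scale` flag switches the test to log2) with
Welch–Satterthwaite degrees of freedom, two-sided p-values, and a
fold-change gate: `hyper` iff fc ≥ 1.5 and p < 0.05, `hypo` iff
fc ≤ 1/1.5 and p < 0.05. No multiple-testing correction is applied at
the probe level (raw p with a fold gate is the convention this
reproduces); BH-FDR is applied only in term enrichment. A numerical
caveat stated plainly: with 4 + 4 samples the Welch test is
intrinsically conservative (true size ≈ 0.041 at nominal 0.05 even for
normal data, because the estimated df never exceeds, and usually falls
below, the pooled df). The suite therefore asserts the one-sided
property — the null rate never exceeds nominal and the joint fold∧p
rate never exceeds the p-only rate — rather than exactness.

Gene aggregation preserves every significant probe row; a gene's
summary direction is reported only when its probes are unanimous,
otherwise `mixed` (real arrays show genes with probes in both
directions). Median classes split genes at 2× above / below the median
control signal, boundaries included. PCA treats samples as
observations and probes as variables, mean-centers columns without
scaling, and fixes signs by making each component's largest-magnitude
loading positive, so scores are reproducible to the bit. Term
enrichment is the hypergeometric upper tail per term with BH adjustment
across terms.

## Bisulfite and HPLC quantification

Per CpG site, percent methylation is 100·C/(C+T) from the trace peak
areas; a region is the unweighted mean over non-missing sites (sites
with both areas 0 are excluded, not imputed). Conversion QC is
ΣT/(ΣC+ΣT) over non-CpG cytosines with a 0.98 pass threshold, and is
reported as *unavailable* — never as a pass — when a trace has no
non-CpG cytosine sites. Region comparisons pool per-site percentages
across replicates within each group and apply the Welch test; sites
within a molecule are not independent, so these p-values carry a
pseudoreplication caveat and should be read as descriptive. The
"completely unmethylated / completely methylated" language of direct
sequencing is operationalized as ≤ 10% / ≥ 90% cuts, with `partial` in
between. HPLC global methylation is the response-factor-corrected area
proportion 100·5mdC/(5mdC+dC) (factors default to 1); a nonzero uracil
peak triggers an RNA-contamination warning but not an error.

## Synthetic data: what it emulates, what it does not

`make_genome` draws background sequence from a first-order Markov chain
whose stationary composition equals the target GC (default 0.40) with
P(G|C) rescaled so the CpG O/E matches the target depletion (default
0.20); the A/G/T rows are solved so the stationary distribution is
exact. Each gene's promoter window receives one island drawn from the
configured GC/O-E/length ranges (defaults 0.55–0.65 / 0.75–0.95 /
250–500 bp), and the island sequence is redrawn until, **in its genomic
context**, the caller reports exactly one island containing the planted
span — this guarantees the truth ledger is recoverable and is part of
the generator's contract, not a test-time convenience. `repeat_fraction`
of the background (never the promoter windows) is lowercased in tracts
of 100–400 bp. All randomness flows through per-operation RNG streams
derived from (seed, operation name), so stages are decoupled and a
fixed config reproduces byte-identical FASTA/GFF3/BED output.

Methylation truth is a two-component mixture: islands are unmethylated
(m ≈ 0.05) or constitutively methylated (m ≈ 0.90) with probability
`baseline_high_prob` = 1/14 — the rate at which a screen of 14 promoter
regions finds one fully methylated. Tumor effects multiply the odds
m/(1−m) by `effect_fold` (default 2.5), downward for hypo and upward
for hyper, which keeps fractions in [0, 1]; on low baselines an
odds-fold is numerically close to a plain fold. Effects are planted on
low-baseline islands: constitutively methylated promoters are stable
between tumor and control in the validation data this emulates, and an
odds-scale shift of a 0.9 baseline (to 0.78) is in any case invisible
at a 1.5-fold signal cut. Per-sample replicate jitter (sd
`replicate_sd` = 0.002 on the fraction scale) models residual
biological variability; it is deliberately small so that measurement
noise is the dominant variance term. Positive/negative control samples
override m to exactly 1/0.

Array signals follow Cy5 = B·(α + β·m)·ε, Cy3 = B·ε′ with per-probe
lognormal affinity B (σ = 0.3) shared across samples and mean-one
lognormal channel noise of CV `noise_cv` (default 0.10). Defaults
α = 5, β = 995 put unmethylated-baseline probes near intensity 55
(above the detection threshold and intensity filter at 25) and the
amplified negative-control sample near 5 (below both), reproducing the
qualitative calibration endpoints of a MeDIP array: uniform low signal
for amplified DNA, uniform high signal for SssI-methylated DNA. With
zero noise, (Cy5/Cy3 − α)/β recovers m exactly — the calibration
invariant the suite asserts.

Not modeled: dye bias, spatial artifacts, between-array variation,
read-level bisulfite chemistry, chromatogram files, fragment-size
effects of sonication, and copy-number variation. Passing tests
therefore demonstrate the pipeline's correctness and its statistical
behavior under a clean multiplicative-noise model, not performance on
real scanner output.

## Problem sizes and determinism

Simulation-based checks use 10,000 probes with 4 + 4 biological
samples for null calibration and recovery, 2,000 probes for the PCA
check, 100 random 2–3 kb sequences for the CGI oracle, and a 500-kb
genome with one engineered 200-bp duplication for the uniqueness-filter
oracle — sizes at which the brute-force oracles remain exact and the
whole suite runs in minutes on one core. Hypothesis-based property
tests run derandomized. `scripts/acceptance.py` derives every stream
from its `--seed` argument and reports, for each quantity, the value
and the problem size it was computed at.

## Known limitations

- The uniqueness filter is exact-match at 55 bp; it will keep a probe
  whose best off-target alignment is 54/55, where a BLAST-based filter
  might remove it.
- Fold changes are computed on group means of normalized ratios; with
  very small groups a single outlying replicate can dominate (the SD
  filter mitigates but does not eliminate this).
- The bisulfite estimator is slightly biased near m = 0 and m = 1
  (clipping of negative peak areas), bounded by ~2 percentage points at
  the default noise level.
- `simulate_bsp_screen` emits one trace per region; replicate-level
  variation in the screen is not simulated because the classification
  it feeds is threshold-based.
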