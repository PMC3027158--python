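# medip-tile

Promoter CpG-island (CGI) tiling arrays for MeDIP methylation profiling
— design and analysis, end to end, with simulators for every input.

DNA methylation at promoter CpG islands silences transcription, and its
disruption (global hypomethylation with focal hypermethylation) is a
hallmark of tumors, including hepatocellular carcinoma in the zebrafish
model. A practical way to profile it genome-wide is methyl-DNA
immunoprecipitation (MeDIP) hybridized against input DNA on a two-color
oligonucleotide array tiled over promoter CGIs. This package implements
that workflow for computational biologists who want to design such an
array or analyze (real or simulated) intensity tables from one:

- **`medip_tile.cgi`** — promoter window extraction (1.5 kb upstream to
  1 kb downstream of each transcript 5′ end, strand-aware) and CGI
  calling by the classic windowed criteria: a 200-bp window qualifies
  when %GC ≥ 50 and the observed/expected CpG ratio
  O/E = (N<sub>CpG</sub>·L)/(N<sub>C</sub>·N<sub>G</sub>) ≥ 0.6; islands
  are maximal runs of covered positions re-checked over their full span.
- **`medip_tile.probes`** — 60-mer probes tiled at 25-bp spacing with a
  right-anchored terminal probe (full coverage), removal of probes whose
  55-mers are not genome-unique (both strands), and an array manifest
  with feature accounting.
- **`medip_tile.chip`** — two-channel analysis: Cy5/Cy3 ratios,
  per-probe normalization to the control-group mean, presence /
  intensity / replicate-SD filters, Welch *t*-tests with a 1.5-fold cut
  for hypo-/hypermethylation calls, gene-level aggregation, 2-fold
  median classes, PCA sample scores, and hypergeometric term enrichment
  with Benjamini–Hochberg FDR.
- **`medip_tile.bsp`** — bisulfite sequencing PCR quantification from
  C/T trace peak areas (per-site percent = 100·C/(C+T), region means,
  conversion QC from non-CpG cytosines, tumor-vs-control comparison)
  and global 5mC percent from HPLC mononucleotide peak areas.
- **`medip_tile.synthetic`** — generators for soft-masked genomes with
  planted promoter CGIs, bimodal methylation landscapes with odds-scale
  tumor effects, two-channel array signals (with fully methylated
  positive and amplified negative control samples), bisulfite traces,
  and HPLC profiles.

## Worked example

Simulate a genome, predict promoter CGIs, design probes, simulate a
hybridization and call differential methylation:

```bash
echo '{"n_chromosomes": 1, "chrom_length": 100000, "n_genes": 8}' > config.json
medip-tile simulate-genome --config config.json --seed 42 --out gen
# wrote genome (1 chromosomes, 8 genes, 8 truth islands) to gen
medip-tile predict-cgi --fasta gen/genome.fa --annotation gen/genes.gff3 --out cgi
# 8 islands in 8 genes -> cgi
medip-tile design-probes --fasta gen/genome.fa --islands cgi/islands.tsv --out design
# 160 tiled, 160 kept, 0 removed -> design
```

Every gene yields one island (they were planted there), e.g. the first
two rows of `cgi/islands.tsv`:

```
gene_id   island_id   chrom  start  end    length  gc     oe
gene0001  gene0001:0  chr1   6135   6706   571     0.543  0.735
gene0002  gene0002:0  chr1   18274  18777  503     0.543  0.688
```

Simulating methylation truth over those islands (3 regions
hypomethylated and 1 hypermethylated in tumors, 4 tumor + 4 control
samples plus the positive/negative control hybridizations) and running
the analysis:

```python
from medip_tile import chip, probes, synthetic

design = probes.read_manifest("design/manifest.tsv")
regions = {}
for p in design.probes:
    regions.setdefault(p.island_ref, synthetic.TruthIsland(
        p.island_ref, p.gene_ids[0], p.chrom, p.start, p.end))
truth = synthetic.make_methylation(
    list(regions.values()), synthetic.default_groups(),
    synthetic.MethylationParams(n_hypo=3, n_hyper=1, seed=42))
channels = synthetic.simulate_array(design, truth, seed=42)
result = chip.run_analysis(channels)
print(result["audit"])
print(len(result["hypo"]), len(result["hyper"]))
```

prints

```
{'input_probes': 160, 'removed_unusable': 0, 'removed_presence': 0,
 'removed_intensity': 0, 'removed_sd': 0, 'retained': 160}
53 24
```

i.e. all 160 probes pass the quality filters, and the 53 hypo / 24
hyper probe calls tile exactly the 3 + 1 planted regions — the hypo
list is larger than the hyper list, as expected when hypomethylation
dominates the planted effects.

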