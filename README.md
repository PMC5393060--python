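# macctools

Analysis toolkit for MNase-titration chromatin profiling. It separates two
properties of chromatin that single-digest MNase-seq conflates:

- **Accessibility (MACC)** — per-bin score derived from the ordinary
  least-squares slope of library-normalized fragment frequency across four
  increasing MNase digestion depths, detrended against bin GC content and
  sign-flipped so accessible chromatin scores positive.
- **Occupancy** — titration-averaged fragment frequency (optionally
  ChIP/input-corrected or input-subtracted), or per-bp coverage from
  pooled-digest libraries.

Downstream analyses include promoter / gene-body / enhancer aggregation with
Mann–Whitney and one-sided signed-rank comparisons, strand-aware metagene
profiles with SEM, H3K27ac enhancer calling (window Z-score vs input, replicate
intersection, promoter exclusion) and time-course classification, stable
nucleosome-position calling with a positional-stability test, and the genome
fraction of significantly changed bins.

A synthetic-digestion simulator (`macctools.synthetic`) generates a small
genome with planted nucleosome occupancy/accessibility, digestion-dependent GC
bias, fragment-length contaminants, enhancer time courses and gene expression
classes, providing ground truth for end-to-end parameter-recovery tests.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the simulation-based acceptance criteria
(parameter recovery, GC-correction efficacy, headline
accessibility-without-occupancy contrast, enhancer recovery, calibrations,
closed-form oracles); the rest are per-module unit and property tests.

## CLI

All pipeline steps are exposed as subcommands of `macctools`; multi-file runs
are wired by a YAML config (flags override config values). Every command
writes a JSON run manifest (parameters, package version, input SHA-256).

```sh
# generate a synthetic data set (genome FASTA, truth tables, fragment BEDs)
macctools simulate --config config.yaml --out simdir

# read-level filters: insert size in [50, 500], anomalous-position Z > 7
macctools filter --in frags.bed --genome genome.fa --out filtered.bed \
    --report report.tsv

# accessibility track from the four titration levels
macctools macc --levels l1.bed l2.bed l3.bed l4.bed --genome genome.fa \
    --out macc.bedgraph

# titration-averaged or pooled-digest occupancy
macctools occupancy --levels l1.bed l2.bed l3.bed l4.bed --genome genome.fa \
    --out occ.bedgraph

# enhancer calling and classification (chip/input pairs listed in the config)
macctools enhancers --config config.yaml --out enhancers.bed

# stable nucleosome positions from pooled coverage
macctools peaks --pooled pooled.bed --genome genome.fa --out peaks.bed

# metagene profile, paired track comparison, significant-change fraction
macctools profile --track macc.bedgraph --genes genes.tsv --out profile.tsv
macctools compare --track-a t0.bedgraph --track-b t4.bedgraph \
    --regions genes.bed --alternative increase --out compare.tsv
macctools fraction --t0 r1.bedgraph --t0 r2.bedgraph \
    --t1 s1.bedgraph --t1 s2.bedgraph --thresholds 0,0.1 --out fraction.tsv
```

Minimal simulate config:

```yaml
seed: 3
output_dir: simdir
depth: 100000
replicates: 2
time_points: [0, 1, 4]
genome:
  chrom_lengths: {chr1: 500000}
  n_genes: 40
  n_enhancers: 8
  accessibility_sd: 0.25
```

## Package layout

| module | contents |
| --- | --- |
| `macctools.tracks` | `Genome`, `FragmentSet`, fixed-grid `BinnedTrack`, per-bp track |
| `macctools.synthetic` | genome/truth builder and titration / ChIP / ATAC / expression simulators |
| `macctools.io_filtering` | BED/BAM fragment parsing, insert-size filter, anomalous-position mask, CPM |
| `macctools.macc` | binning, titration slope, GC correction, occupancy variants, quantile scaling |
| `macctools.features` | gene classes, regions, metagene profiles, rank tests, change fractions |
| `macctools.enhancers` | window enrichment, region calling/merging, replicate intersection, classification |
| `macctools.peaks` | nucleosome-position calling and positional-stability comparison |
| `macctools.stats` | exact / asymptotic Mann–Whitney and Wilcoxon signed-rank implementations |
| `macctools.cli` | subcommands, YAML `RunConfig`, run manifests |
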