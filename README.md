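# mutevol

Analysis toolkit for mutation-accumulation (MA) experiments in microbes:
from filtered per-line variant calls to mutation-rate estimates, effective
population sizes, contextual mutation spectra, NMF-derived mutation
patterns, fluctuation-test mutation rates, and genomic-divergence rates.
A synthetic-data generator produces every input the pipeline consumes, so
the full stack is testable without sequencing data.

## Modules

| module | what it does |
| --- | --- |
| `mutevol.io` | FASTA, minimal-VCF call tables, TSV tables, config, logging |
| `mutevol.simulate` | random genomes, MA call sets with a 96-class context spectrum and injected filter-test artifacts, Lea-Coulson fluctuation assays, divergence series |
| `mutevol.filtering` | depth/quality filters, ancestral subtraction, cross-line consensus removal, windowed multi-caller SV dedup, parallel-line SV screening |
| `mutevol.rates` | generations per passage, per-site and per-genome rates, Z-score outlier exclusion, group fold changes + Welch t-tests |
| `mutevol.demography` | serial-transfer census trajectories, harmonic-mean Ne, generations per day |
| `mutevol.spectra` | pyrimidine-centered 6-class and 96-class trinucleotide spectra |
| `mutevol.patterns` | NMF mutation patterns (generalized-KL multiplicative updates), cophenetic rank selection, correlation with reference signatures |
| `mutevol.fluctuation` | Luria-Delbrueck mutant-count distribution (Ma-Sandri-Sarkar recursion) and maximum-likelihood rate estimation |
| `mutevol.divergence` | divergence from allele frequencies; zero-intercept regression slope |

## Command line

`mutevol` exposes one subcommand per stage; every stochastic command takes
an explicit `--seed`:

```sh
# simulate an MA experiment and push it through filter + rates
mutevol simulate ma --genome-length 100000 --snm-rate 1e-7 --sim-rate 2e-8 \
    --n-lines 25 --seed 1 --out-calls calls.vcf --out-lines lines.tsv \
    --out-fasta genome.fa --out-truth truth.tsv
mutevol filter --calls calls.vcf --out-kept kept.vcf --out-removed removed.tsv
mutevol rates --calls kept.vcf --lines lines.tsv --out rates.tsv \
    --out-summary summary.tsv

# demography of a serial-dilution regime
mutevol ne --dilution 1e-4 --period-days 1 --capacity 1e10

# contextual spectra and NMF patterns
mutevol spectrum --calls kept.vcf --fasta genome.fa --out spectrum.tsv
mutevol spectrum --calls kept.vcf --fasta genome.fa --per-line --out matrix.tsv
mutevol patterns --matrix matrix.tsv --rank-range 2-6 --seed 1 --out-prefix mp

# fluctuation tests
mutevol simulate fluctuation --mu 5e-9 --n-final 1e9 --seed 1 --out assay.tsv
mutevol fluctuation estimate --assay assay.tsv --out estimate.tsv

# divergence slope
mutevol simulate divergence --slope 0.01 --timepoints 0,100,200,300 \
    --noise-sd 0.1 --seed 1 --out series.tsv
mutevol divergence --series series.tsv --out slope.tsv

# one-config full run (simulate -> filter -> rates)
mutevol run --config config.yaml --out-prefix out/run1
```

A `run` config is a YAML mapping with `seed`, `simulate`, `filter`, and
`rates` sections, e.g.

```yaml
seed: 1
simulate: {genome_length: 100000, snm_rate: 1.0e-7, n_lines: 25}
filter: {min_depth: 4, min_qual: 10}
rates: {zscore_cutoff: 2.5}
```

## Conventions

- Coordinates are 1-based, closed intervals, VCF-style, everywhere.
- Call tables are a minimal VCF dialect: `CHROM POS ID REF ALT QUAL FILTER
  INFO`, with the line identifier in INFO key `LINE`, depth in `DP`, and
  SVs described by `SVTYPE`/`SVSTART`/`END`/`SOURCE`; unknown INFO keys are
  preserved verbatim.
- Mutation classes: SNM (single-nucleotide), SIM (indels of at most 4 bp),
  SV (everything larger). SNM/SIM rates are per site per generation;
  SV rates are per genome per generation.
- The serial-transfer census convention is doublings from the bottleneck
  `K*D` strictly below the carrying capacity, then the carrying capacity
  itself; Ne is the harmonic mean of those snapshots. For a 1/10^7 daily
  dilution at K = 1e10 this yields Ne ~ 1.3e4 (not 1.3e3 as sometimes
  quoted; the same convention reproduces the 1/10 and 1/10^4 values
  exactly).
- Generations per day is `log2(1/D) / T`; for the 100-day transfer regime
  this gives 0.033, not the occasionally quoted 0.25, which is not
  derivable from the dilution alone and is not reproduced here.
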