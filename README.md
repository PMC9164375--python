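# linevar

Analysis toolkit for **rare and population-specific functional variation
across closed breeding lines** (pig, cattle, chicken, … — any set of diverged
populations genotyped against one variant index).

Breeding programmes maintain multiple genetically isolated lines. Sequencing
them jointly raises questions this package answers quantitatively:

* How are variants distributed across lines? Each variant gets a
  **prevalence level** *k* — the number of lines in which it segregates
  (*k* = 1 "private", *k* = L "widespread") — and a per-site differentiation
  index among the segregating lines,

  F<sub>ST</sub> = (H<sub>T</sub> − H<sub>S</sub>) / H<sub>T</sub>,

  with H<sub>T</sub> = 2p̄(1 − p̄) the expected heterozygosity of the mean
  line frequency and H<sub>S</sub> the mean within-line expected
  heterozygosity, both under Hardy–Weinberg equilibrium.
* Which variants are putatively functional? Sequence Ontology annotations
  are resolved to a single most-severe category on a fixed severity scale
  (loss-of-function → … → intergenic), with frameshift indels kept as a
  separate category, missense split by SIFT score (< 0.05 deleterious), and
  upstream variants within 500 bp of the transcription start site moved into
  the promoter/5′UTR category.
* How many functional alleles does an individual carry? Per-individual
  **load** = counts and percentages of each category carried heterozygous or
  homozygous for the alternative allele, on samples of up to 50,000 variants
  per category.
* Which variants associate with traits? A univariate linear mixed model
  y = x<sub>i</sub>β<sub>i</sub> + u + e with u ~ N(0, σ²<sub>u</sub>K),
  K the VanRaden genomic relationship matrix, solved through one spectral
  decomposition of K so every variant test is linear-time. Per-variant
  explained variance is 2pq β̂² as a percentage of phenotypic variance.
* Which variant represents an associated region? Haplotype blocks are
  defined from the 90% confidence interval of |D′| (strong LD: lower bound
  > 0.7 and upper bound ≥ 0.9; ≥ 90% of informative pairs within 5 Mb), and
  each block's candidate is its most severe significant variant, lowest
  p-value on ties. Category enrichment is the log ratio of
  significant/non-significant odds against the genome-wide odds.

A **synthetic cohort generator** (Balding–Nichols line divergence, injected
private variants, purifying-selection frequency shifts,
recombination-coupled variant density, sparse causal + polygenic
phenotypes) provides ground-truth data for every stage and powers the test
suite.

## Worked example

Simulate a three-line cohort and compute per-site statistics:

```sh
linevar simulate --out demo --seed 42 --lines 3 --variants 2000 --individuals 50
linevar stats demo/line_A.vcf demo/line_B.vcf demo/line_C.vcf \
    --map demo/recomb_map.tsv --out demo/site_stats.tsv
```

which prints

```
density~rate (all): r=0.961 p=1.84e-11
density~rate (private): r=0.776 p=5.75e-05
density~rate (widespread): r=0.802 p=2.14e-05
```

— variant density in 1-Mb windows tracks the recombination rate, as the
generator's placement model intends. The site-stats table then stratifies
the cohort (counts from this run: 579 private, 189 intermediate, 603
widespread, 629 non-segregating) and gives a mean per-site F<sub>ST</sub> of
0.114 among variants segregating in at least two lines. Private variants
have markedly lower frequencies and (where defined) lower F<sub>ST</sub>
than widespread ones — the central empirical pattern this toolkit is built
to quantify.

Other subcommands: `linevar load` (per-individual allele load),
`linevar gwas` (mixed-model scan), `linevar blocks` (D′ haplotype blocks and
candidates), `linevar enrich` (category enrichment scores). All accept a
TOML config mirroring `AnalysisConfig` and echo the seed and thresholds as
`#` metadata lines in every output table.

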