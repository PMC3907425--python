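# genespace

A tested, reusable pipeline for analysing methylation-filtered (gene-enriched)
shotgun libraries against unfiltered controls, driven end to end by a
synthetic-data generator so every stage is verifiable without external
downloads. It covers:

- **Filter power & effective genome size** — the direct gene-hit probability
  ratio between filtered and unfiltered libraries, and an independent
  estimate from inverting a piecewise Lander–Waterman island-count
  expectation for a mixed two-density assembly (`genespace.filterpower`).
- **Island statistics** — single-linkage overlap clustering of placed reads
  into islands (contigs + singletons), N50 and assembly summary tables
  (`genespace.islands`).
- **SSR mining** — di/tri/tetranucleotide microsatellites with minimum unit
  counts 6/5/4 and an imperfection budget of one per ten units, plus
  canonical motif classes under rotation/reverse-complement equivalence
  (`genespace.ssr`).
- **SNP calling** — pileup interrogation with a ≥2-reads-per-allele support
  rule and a high-coverage depth cutoff, substitution spectra, Ti/Tv ratios
  and SNP density (`genespace.snp`).
- **Gene-space coverage & classification** — iterative align-and-mask
  subtraction, EST tagging and gene-model QC thresholds, R-gene domain
  signature classes 1–6 and miRNA match classification
  (`genespace.coverage`).
- **Simulation & I/O** — genomes with gene/repeat/methylated annotation,
  filtered/unfiltered read libraries, variant truth sets and multi-read
  pileups (`genespace.synthetic`); FASTA, ACE (documented subset), VCF,
  GFF3 and TSV readers/writers (`genespace.formats`).

## Command line

One executable with subcommands; global flags `--config` (YAML mirroring any
flag), `--seed`, `--log-level`, `--out-dir`:

```bash
genespace --out-dir run1 simulate --length 100000 --n-reads 5000
genespace --out-dir run1 islands --placements run1/placement_filtered.tsv
genespace --out-dir run1 filterpower direct --filtered-hits 40 --filtered-total 100 \
    --unfiltered-hits 20 --unfiltered-total 100 --genome-mb 1800
genespace --out-dir run1 filterpower lw --islands 4200 --nf 2500 --nu 2500 \
    --read-len 100 --genome-mb 1
genespace --out-dir run1 ssr --fasta run1/genome.fasta
genespace --out-dir run1 snp --ace pileups.ace
genespace --out-dir run1 coverage --queries ests.fasta --targets genes.fasta
genespace --out-dir run1 classify --domains domains.tsv
```

Every stage logs input/filter/output counts and writes a machine-readable
`<stage>_summary.json` next to its outputs.

## Conventions

- Coordinates are 0-based half-open everywhere in memory; the +1 shift to
  1-based closed output happens exactly once, at serialization.
- All generators and writers are deterministic: identical seeds and
  parameters yield byte-identical outputs.
- The bundled local aligner's score→e-value mapping is a monotone
  pseudo-significance, documented as **not** BLAST-compatible; production
  subtraction runs should supply external tabular hit files.
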