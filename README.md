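# bsakit

Bulked-segregant mapping of a recessive locus from pooled sequencing, end to
end and fully offline. The package simulates an F2 intercross with
phenotype-based pooling, scans the genome with per-SNP allele-frequency
differentiation (dAF) and pooled-heterozygosity (Hp) windows, calls candidate
intervals from the empirical top fraction, prioritizes annotated variants down
to a causal candidate, predicts the transcript consequences of a splice-donor
mutation (cryptic GT donors, intron-retention isoforms, frame/stop status),
and quantifies isoform abundance from barcoded noisy long reads.

## Modules

| module       | what it does |
| ------------ | ------------ |
| `simcross`   | synthetic F2-cross pool-seq data: founder SNP grids, Haldane recombination, phenotype pooling with optional misclassification, Poisson/binomial read counts, reference panels, barcoded amplicon reads |
| `poolscan`   | per-SNP dAF, SNP-rank windows of mean dAF and Hp, wild-type/mutant Hp ratio, empirical top-fraction thresholds, merged BED intervals |
| `candfilter` | prioritization cascade: region, quality/biallelic, depth cap, impact class, dAF > 0.5, panel absence; ranked candidate report |
| `splicefx`   | gene models, donor-disruption check, cryptic GT donor scan, intron-retention isoforms, peptide-level consequences |
| `isoquant`   | exact-prefix barcode demultiplexing, junction-signature read classification (semi-global edit distance), abundance tables |
| `crossstats` | segregation vs Mendelian expectation (exact binomial), genotype/phenotype concordance, expected pool dAF under the recessive model, -dCq |

## Command line

```sh
# simulate a mapping dataset (pooled VCF + panel TSV), scan it, filter it
bsakit simulate bsa --seed 1 --out-vcf pools.vcf --out-panel panel.tsv
bsakit scan --vcf pools.vcf --window-snps 500 --step-snps 100 --min-snps 400 \
      --stat hp-ratio --out-windows windows.tsv --out-bed interval.bed
bsakit filter --vcf pools.vcf --panel panel.tsv --interval interval.bed \
      --out-report cascade.tsv --out-candidates candidates.tsv

# splice consequences and long-read isoform quantification
bsakit splice --gene gene.json --intron-index 1 --variant chr1:251:G:A --out isoforms.tsv
bsakit simulate amplicons --seed 2 --out-fastq reads.fastq --out-signatures sigs.json
bsakit quant --fastq reads.fastq --barcodes barcodes.tsv --signatures sigs.json --out abundance.tsv

# cross-level statistics
bsakit stats segregation --n-affected 12 --n-total 52
bsakit stats expected-daf
```

All subcommands log their parameters and seeds to standard error. Pooled
counts travel as a two-sample (MUT, WT) VCF carrying AD/DP or an equivalent
TSV; intervals are BED (0-based half-open); gene models are compact JSON.

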