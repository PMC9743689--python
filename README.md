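# ctsplice

Co-transcriptional splicing analysis for chromatin-bound RNA-seq (CB-RNA-seq).

Chromatin-bound RNA — the RNA that co-purifies with chromatin after stringent
urea washes — is dominated by nascent transcripts still attached to RNA
polymerase II, plus a small population of polyadenylated transcripts not yet
released from chromatin. Sequencing it reveals how much splicing happens
*while genes are being transcribed*: introns that are usually removed before
the polymerase finishes leave little intronic signal, retained introns leave
a lot. `ctsplice` implements the standard analysis of such libraries for
intron-rich, compact genomes like *Arabidopsis thaliana*, together with a
mechanistic read simulator that provides exact ground truth for validating
every statistic.

## The statistic

At each intron boundary of a gene's representative transcript (its longest
isoform by summed exon length), the **splice-site ratio** compares coverage
of the two adjacent bases:

```
5'SS ratio = cov(first intronic base) / cov(last base of upstream exon)
3'SS ratio = cov(last intronic base)  / cov(first base of downstream exon)
```

Reads spliced across the intron carry an N-skip in their CIGAR and cover only
the exonic side, so the ratio estimates the unspliced fraction *u* of
molecules at that junction: 0 = fully co-transcriptionally spliced, 1 =
fully retained. It is therefore negatively correlated with splicing
efficiency. A gene's ratio is the unweighted mean over its introns' defined
ratios; genes are kept when FPKM ≥ 1, with
FPKM = fragments × 10⁹ / (exonic length × total mapped fragments).
Multi-mapping reads are excluded; counting is unstranded by default.

Around this core the package provides:

* **annotation** — GTF/GFF3 → exact 0-based gene/transcript/exon/intron model,
  representative-transcript selection, junction tables (TSV/BED6);
* **alignments** — SAM/BAM ingestion (pysam), CIGAR-resolved aligned blocks
  (M/=/X/D extend a block, N splits it), fast columnar coverage queries;
* **metrics** — boundary counting, splice-site ratios, FPKM filter,
  intron/exon depth ratio, intron-order and intron-number stratification,
  Wilcoxon rank-sum comparisons, qPCR unspliced/spliced ratios;
* **metagene** — 5-bp windowed TPM-scaled tracks, TSS→PAS scaled gene-body
  profiles, profile slope (Spearman of bin index vs bin mean);
* **simulate** — generative model of the three chromatin RNA classes
  (elongating RNAe truncated at a uniform polymerase position with
  distance-dependent splicing 1 − e^(−d/λ); polyadenylated-but-unreleased
  RNAf with per-intron retention r; mature mRNA), emitting coordinate-sorted
  SAM/BAM and an exactly enumerable truth table.

## Worked example

```python
from ctsplice import SimConfig, simulate_dataset, summarize_genes, compare_fractions
import numpy as np

cb = simulate_dataset(SimConfig(n_genes=40, depth=150, molecules_per_gene=400,
                                fraction_mix={"mRNA": 0, "RNAe": 0.9, "RNAf": 0.1},
                                seed=2))
per_intron, per_gene = summarize_genes(cb.gene_set, cb.reads)
print(np.nanmedian(per_gene["mean_5p"]), np.nanmedian(per_gene["mean_3p"]))
```

prints `0.244 0.154`: in a chromatin-like library (90% elongating + 10%
polyadenylated molecules) the median gene retains about a quarter of its
intronic signal at 5' splice sites — the hallmark of widespread but
incomplete co-transcriptional splicing. The same pipeline on a pure-mRNA
simulation gives exactly `0.0 0.0`, and comparing the two gene-level
distributions with `compare_fractions` yields p ≈ 2×10⁻¹⁶. The scripts in
`examples/` walk through each capability (simulation with ground truth,
ratio tables, metagene slopes of −0.99 for nascent vs +0.16 for mature
libraries, order/number stratification, qPCR ratios) and print what every
number means.

A thin CLI mirrors the library:

```bash
ctsplice simulate --out-dir sim --seed 1
ctsplice annotate-introns --gtf sim/genes.gtf --out introns.tsv
ctsplice ss-ratio --gtf sim/genes.gtf --bam sim/reads.sam --out genes.tsv
ctsplice metagene --gtf sim/genes.gtf --bam sim/reads.sam --out profile.tsv
```

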