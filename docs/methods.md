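# Methods

## The measurement model

Chromatin-bound RNA libraries mix three molecule classes: **RNAe**,
elongating transcripts still held by RNA polymerase II and truncated at the
polymerase position; **RNAf**, transcripts that are fully transcribed and
polyadenylated but not yet released from chromatin; and residual mature
**mRNA**. `ctsplice` quantifies co-transcriptional splicing through the
splice-site ratio: at an intron boundary, the coverage of the first (5'SS)
or last (3'SS) intronic base divided by the coverage of the single adjacent
exonic base. Because a spliced read's N-skip removes all intronic bases from
its aligned blocks, the intronic count samples only molecules in which the
intron is still present, while the exonic count samples all molecules
covering the boundary; the ratio is therefore a plug-in estimator of the
unspliced fraction *u* at that junction.

Single-base adjacency makes the numerator essentially a subset of the
denominator — the two counts differ only through reads whose alignment
starts or ends exactly at the splice site — so conditional on the total
boundary coverage *n* the estimate behaves like a Binomial(*n*, *u*)
proportion. The boundary-edge reads add a further variance term of order
*u*(4*u* − 1)/(*R·n*) for read length *R*; it is negligible against
*u*(1 − *u*)/*n* through most of the range but dominates as *u* → 1, where
the binomial term vanishes. Two practical consequences, both visible in the
test suite: recovery of simulated truth holds to 3σ binomial bands at ≥99%
of junctions but not at literally every near-fully-retained junction, and at
*u* = 1 exactly the residual noise is Var ≈ 2/(*n·R*) (two independent
Poisson edge-read counts of rate *n*/*R* entering numerator and denominator
asymmetrically), which is the band used for the fully retained limit.

Aggregation follows the field's standard recipe: one representative
transcript per gene (maximal spliced length; ties broken by smallest
transcript id), genes kept at FPKM ≥ 1, gene ratio = unweighted mean of the
defined per-intron ratios, undefined ratios (zero exonic coverage) skipped
rather than imputed. FPKM counts distinct fragments overlapping the
representative exons by ≥1 bp against all filtered fragments in the library;
this self-contained definition replaces the external assembler a full
pipeline would use and is documented as a dialect. Read filtering excludes
unmapped/secondary/supplementary records and any alignment whose hit-count
tag exceeds 1; duplicates are kept (no dedup step is part of the reproduced
protocol) and counting is unstranded by default, with sense/antisense modes
behind a flag, because antisense transcription is rare in the target genome.

## The simulator

The generator is the package's instrument for validating every stage without
external data, and its defaults are chosen to emulate a chromatin-bound
library of a compact plant genome:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 50 | genes on one synthetic chromosome, ≥500 bp apart, random strands |
| `exon_count_range` | (2, 10) | exons per transcript, uniform inclusive |
| exon lengths | lognormal, median ≈ 220 bp | TAIR-like exons |
| intron lengths | lognormal, median ≈ 150 bp | TAIR-like introns |
| `utr5_length` / `utr3_length` | 110 / 220 bp | added to terminal exons; Arabidopsis-scale UTRs |
| `read_length` | 150 bp | the platform read length of the emulated libraries |
| `depth` | 50 | target coverage at positions covered by all of a gene's molecules |
| `molecules_per_gene` | 300 | granularity of the enumerable truth |
| `fraction_mix` | mRNA 0, RNAe 0.9, RNAf 0.1 | RNAf is a small fraction of chromatin RNA |
| `maturation_length` λ | 300 bp | polymerase travel past an intron's 3'SS for splicing probability 1 − e^(−d/λ) |
| `rnaf_retention` r | 0.05 | per-intron retention in the polyadenylated fraction |
| `cooperativity` c | 1.5 | an already-spliced 5' neighbour multiplies the splicing rate (RNAe) or divides retention (RNAf) |
| `three_prime_bias` β | 0 | mRNA fragment-position skew toward the 3' end |

RNAe molecules draw a polymerase position uniformly along the pre-mRNA;
introns are decided in transcription order — not yet fully transcribed
introns are present up to the truncation point, fully transcribed ones are
spliced with probability 1 − e^(−d·c^k/λ) where *d* is the distance
transcribed past the 3'SS and *k* ∈ {0, 1} flags a spliced upstream
neighbour. This minimal distance-dependent mechanism produces the
first-come-first-serve order trend and the near-linear 5'→3' coverage
decline; uniform polymerase positions are deliberate (promoter-proximal
pausing is not resolved by this library type and is not modelled).
λ = 300 bp was calibrated once so that the default mixture reproduces a
median gene splice-site ratio of ≈0.25, the level observed on chromatin in
the emulated experiments; analyses of the order trend use λ of the order of
the gene length, where the trend is steepest. The UTR extensions matter more
than they look: without them, short terminal exons put last-intron junctions
at *u* ≈ 0.995 under gene-length-scale λ, a regime where the boundary-edge
noise floor exceeds any binomial band.

Reads are `read_length` fragments at Poisson-distributed, uniform positions
over the molecule *including clipped end fragments*, so every base of every
molecule has identical expected coverage (exactly *R* start positions).
This is not cosmetic: if fragments were only placed where a full read fits,
junctions near a molecule's 3' end — systematically the recently
transcribed, unspliced ones — would be under-covered and the ratio biased.
Fragments are lifted from molecule to genome coordinates through the
molecule's splice state, producing multi-block records whose N-skips equal
the spliced intron lengths exactly; a round-trip identity test inverts the
lift for every read. Sequencing error, base qualities and PCR duplicates are
not simulated — the statistics depend only on coordinates — and molecules
shorter than one read are skipped and counted.

Ground truth is enumerable: for each junction side the truth table reports
the fraction of emitted molecules presenting the adjacent intronic base
unspliced among those presenting the adjacent exonic base — exactly the
molecule sets the coverage ratio samples. The two sets differ for a
polymerase stopped precisely at the 3' splice site (it has made the last
intronic base but not the exonic one, and with zero travel it is always
unspliced), so at an almost-fully-retained junction the truth, like the
measured ratio, can marginally exceed 1.

### What the simulator does not emulate

No sequence-level realism beyond valid records (splice-site motifs, GC
effects, mappability), no rRNA or poly(A)-selection artefacts, no
promoter-proximal pausing, no paired-end inserts (each fragment yields one
read; FPKM treats a read as a fragment), no duplicate or error structure, no
overlapping or nested genes. Tests passing on this generator therefore
validate the *statistical* machinery — counting semantics, estimator
calibration, trend directions — not robustness to alignment artefacts of
real libraries.

## Other numerical choices

* Coordinates are 0-based half-open internally; GTF/GFF3 read as 1-based
  inclusive; BED/bedGraph written 0-based half-open.
* Windowed tracks are tiled (stride = window size, default 5 bp) and scaled
  by 10⁶ / total aligned bases, so the genome-wide sum of value × window
  length is 10⁶; the scaling constant is carried on the track.
* Metagene profiles rescale each gene body (TSS→PAS, strand-aware) onto 100
  bins by averaging per-base window values; genes shorter than
  max(10 × window, n_bins) are skipped. The slope is a Spearman correlation;
  a constant profile is reported as 0 with a degenerate flag.
* Rank-sum comparisons use exact enumeration for combined n ≤ 20 without
  ties and the tie-corrected normal approximation otherwise; an all-tied
  comparison returns p = 1.
* The boundary-count window option averages coverage over N flanking bases
  per side; the default is the strict single-base definition.
* qPCR ratios use efficiency 2.0 per cycle by default:
  ratio = E^(Ct_spliced − Ct_unspliced).

## Problem sizes

The statistical tests run seeded simulations sized to keep the full suite
around two minutes on one core: estimator recovery uses 5 replicates of 30
genes at boundary coverage ~2000 with 3000 molecules/gene (≈1M reads each);
distributional checks (fraction ordering across 20 seeds, order trend,
metagene contrast) use 30–60 genes at coverage 100–200. The acceptance
script uses 40-gene libraries at coverage 150 plus a reduced recovery run,
finishing in well under a minute.

## Known limitations

The FPKM dialect and the TPM track scaling are self-contained definitions,
not byte-compatible with any particular external tool. GTF parsing infers
gene/transcript parents only through gffutils' standard attribute
conventions. The exact-Wilcoxon path requires tie-free data (scipy's exact
method); tied small samples fall back to the corrected normal approximation.
Single-base boundary counting is exact but noisy at junctions with extreme
retention, as quantified above; the window option trades a little locality
for variance when needed.
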