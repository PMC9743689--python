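"""Mechanistic simulator of chromatin-bound RNA-seq libraries.

The generator emits reads from a mixture of three molecule classes observed
on chromatin:

* **RNAe** — elongating transcripts truncated at a polymerase position drawn
  uniformly along the pre-mRNA.  An intron whose 3' splice site lies ``d``
  bases upstream of the polymerase has been spliced with probability
  ``1 - exp(-d / lambda)`` (``lambda`` = maturation length): splicing takes
  polymerase travel, so 5' introns — transcribed first — are more often
  already removed ("first come, first serve").
* **RNAf** — full-length, polyadenylated molecules still on chromatin; each
  intron is retained with a small probability ``r`` (processing
  intermediates).
* **mRNA** — mature, fully spliced molecules, optionally with a 3' fragment
  bias ``beta``.

Cooperativity ``c`` couples neighbouring introns: an already-spliced 5'
neighbour multiplies the splicing rate (RNAe) or divides the retention
probability (RNAf) by ``c``, producing the negative trend of retention with
intron number.

Reads are uniform fragments of the processed molecule lifted back to genomic
coordinates, so reads across a spliced junction become multi-block records
with an N skip of exactly the intron length.  Ground truth — the per-junction
unspliced fraction among boundary-covering molecules — is recomputable by
exhaustive enumeration of the emitted molecules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .alignments import ReadBlocks
from .annotation import Gene, GeneSet, Intron, Transcript

__all__ = [
    "SimConfig",
    "TranscriptMolecule",
    "SimTruth",
    "simulate_genome",
    "simulate_molecules",
    "simulate_reads",
    "simulate_dataset",
    "true_retention",
    "write_fasta",
    "SPLICED",
    "RETAINED",
    "NOT_YET",
]

SPLICED, RETAINED, NOT_YET = 0, 1, 2
_STATE_NAMES = {SPLICED: "spliced", RETAINED: "retained", NOT_YET: "not_yet_transcribed"}
_FRACTIONS = ("mRNA", "RNAe", "RNAf")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults emulate a chromatin-bound library
    of a compact plant-like genome (short exons and introns, 2-10 exons per
    gene, elongating molecules dominating with a small polyadenylated
    fraction)."""

    n_genes: int = 50
    exon_count_range: Tuple[int, int] = (2, 10)  # inclusive
    exon_length_log_mean: float = 5.4   # ln bp; median ~ 220 bp
    exon_length_log_sd: float = 0.45
    intron_length_log_mean: float = 5.0  # median ~ 150 bp
    intron_length_log_sd: float = 0.35
    min_exon_length: int = 50
    min_intron_length: int = 60
    utr5_length: int = 110  # added to the transcription-first exon
    utr3_length: int = 220  # added to the transcription-last exon
    read_length: int = 150
    depth: float = 50.0  # target coverage where all molecules overlap (gene 5' end)
    molecules_per_gene: int = 300
    fraction_mix: Dict[str, float] = field(
        default_factory=lambda: {"mRNA": 0.0, "RNAe": 0.9, "RNAf": 0.1}
    )
    maturation_length: float = 300.0  # lambda, bp; see docs/methods.md
    rnaf_retention: float = 0.05  # r
    cooperativity: float = 1.5  # c
    three_prime_bias: float = 0.0  # beta; mRNA fragment-position skew
    gene_spacing: int = 500
    chrom: str = "chr1"
    chrom_length: Optional[int] = None  # None: sized to fit the genes
    seed: int = 0

    def __post_init__(self) -> None:
        weights = [self.fraction_mix.get(f, 0.0) for f in _FRACTIONS]
        if any(w < 0 for w in weights) or not math.isclose(sum(weights), 1.0):
            raise ValueError("fraction_mix weights must be >= 0 and sum to 1")
        if self.maturation_length <= 0:
            raise ValueError("maturation_length must be > 0")
        if not 0 <= self.rnaf_retention <= 1:
            raise ValueError("rnaf_retention must be in [0, 1]")
        if self.exon_count_range[0] < 2 or self.exon_count_range[1] < self.exon_count_range[0]:
            raise ValueError("exon_count_range must be (lo, hi) with 2 <= lo <= hi")

    @property
    def mix_weights(self) -> np.ndarray:
        return np.array([self.fraction_mix.get(f, 0.0) for f in _FRACTIONS])


@dataclass(frozen=True)
class TranscriptMolecule:
    """One emitted molecule: its class, polymerase position (bases of
    pre-mRNA transcribed; full length except for RNAe), and per-intron
    splice state in transcription order."""

    gene_id: str
    fraction: str  # mRNA | RNAe | RNAf
    pol_position: int
    splice_state: tuple  # ints: SPLICED / RETAINED / NOT_YET

    @property
    def state_names(self) -> tuple:
        return tuple(_STATE_NAMES[s] for s in self.splice_state)


class _GeneLayout:
    """Pre-mRNA coordinate system of one representative transcript."""

    def __init__(self, gene: Gene):
        tx = gene.representative_transcript
        self.gene_id = gene.id
        self.chrom = gene.chrom
        self.strand = gene.strand
        self.g_start, self.g_end = tx.span
        introns = tx.introns  # transcription order
        exon_lens = [e - s for s, e in tx.exons]
        if gene.strand == "-":
            exon_lens = exon_lens[::-1]
        intron_lens = [iv.length for iv in introns]  # transcription order
        self.k = len(introns)
        self.introns = introns
        # features in transcription order: (p_start, p_end, intron_index or -1)
        self.features: List[Tuple[int, int, int]] = []
        self.t_start = np.zeros(self.k, dtype=np.int64)
        self.t_end = np.zeros(self.k, dtype=np.int64)
        p = 0
        for i, elen in enumerate(exon_lens):
            self.features.append((p, p + elen, -1))
            p += elen
            if i < self.k:
                ilen = intron_lens[i]
                self.t_start[i], self.t_end[i] = p, p + ilen
                self.features.append((p, p + ilen, i))
                p += ilen
        self.pre_len = p

    def to_genomic(self, p_lo: int, length: int) -> Tuple[int, int]:
        """Map a pre-mRNA interval [p_lo, p_lo+length) to a genomic block."""
        if self.strand == "+":
            g = self.g_start + p_lo
            return g, g + length
        g_hi = self.g_end - p_lo
        return g_hi - length, g_hi


class SimTruth:
    """Ground truth of one simulated library.

    Holds every emitted molecule plus the gene layouts; the per-junction true
    unspliced fraction is recomputed by exhaustive enumeration on demand.
    """

    def __init__(self, layouts: Dict[str, _GeneLayout],
                 molecules: List[TranscriptMolecule],
                 n_short_skipped: int = 0):
        self._layouts = layouts
        self.molecules = molecules
        self.n_short_skipped = n_short_skipped

    @property
    def fraction_counts(self) -> Dict[str, int]:
        counts = {f: 0 for f in _FRACTIONS}
        for mol in self.molecules:
            counts[mol.fraction] += 1
        return counts

    def retention(self, intron: Intron, side: str = "5p") -> tuple:
        """(true unspliced fraction, n boundary-covering molecules).

        The denominator counts molecules presenting the adjacent *exonic*
        base, the numerator those presenting the adjacent *intronic* base
        unspliced — exactly the molecule sets the coverage ratio samples.
        The two sets differ for a molecule truncated precisely between the
        two bases (a polymerase stopped exactly at the 3' splice site), so
        at an almost-fully-retained junction the fraction can marginally
        exceed 1, as the measured ratio itself can.
        """
        layout = self._layouts[intron.gene_id]
        i = intron.order - 1
        t_start, t_end = int(layout.t_start[i]), int(layout.t_end[i])
        if side not in ("5p", "3p"):
            raise ValueError(f"side must be '5p' or '3p', got {side!r}")
        covering = unspliced = 0
        for mol in self.molecules:
            if mol.gene_id != intron.gene_id:
                continue
            pol, state = mol.pol_position, mol.splice_state[i]
            if side == "5p":
                # exonic base: pre-mRNA coord t_start - 1; intronic: t_start
                covering += pol >= t_start
                unspliced += state != SPLICED and pol >= t_start + 1
            else:
                # exonic base: pre-mRNA coord t_end; intronic: t_end - 1
                covering += pol >= t_end + 1
                unspliced += state == RETAINED and pol >= t_end
        frac = unspliced / covering if covering else math.nan
        return frac, covering

    def table(self, gene_set: GeneSet) -> pd.DataFrame:
        rows = []
        for intron in gene_set.representative_introns():
            for side in ("5p", "3p"):
                u, n = self.retention(intron, side)
                rows.append({"gene": intron.gene_id, "order": intron.order,
                             "side": side, "true_unspliced_fraction": u,
                             "n_covering_molecules": n})
        return pd.DataFrame(rows)


def true_retention(truth: SimTruth, intron: Intron, side: str = "5p") -> float:
    """Exact unspliced fraction among boundary-covering molecules."""
    if intron.gene_id not in truth._layouts:
        raise KeyError(f"unknown intron: gene {intron.gene_id!r} not in truth")
    return truth.retention(intron, side)[0]


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig,
                    rng: Optional[np.random.Generator] = None) -> Tuple[str, GeneSet]:
    """Sample a synthetic chromosome and non-overlapping gene models.

    Genes are laid out left to right with ``gene_spacing`` between them and
    assigned random strands; exon/intron lengths are log-normal with a floor.
    Deterministic for a given config (the rng defaults to the config seed).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gene_set = GeneSet(source_dialect="GTF")
    pos = config.gene_spacing
    lo, hi = config.exon_count_range
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = np.maximum(
            rng.lognormal(config.exon_length_log_mean, config.exon_length_log_sd,
                          n_exons).astype(int),
            config.min_exon_length,
        )
        strand = "+" if rng.random() < 0.5 else "-"
        # terminal exons carry the UTRs (transcription-first / -last)
        first_i, last_i = (0, n_exons - 1) if strand == "+" else (n_exons - 1, 0)
        exon_lens[first_i] += config.utr5_length
        exon_lens[last_i] += config.utr3_length
        intron_lens = np.maximum(
            rng.lognormal(config.intron_length_log_mean, config.intron_length_log_sd,
                          n_exons - 1).astype(int),
            config.min_intron_length,
        )
        exons = []
        p = pos
        for i, elen in enumerate(exon_lens):
            exons.append((p, p + int(elen)))
            p += int(elen)
            if i < n_exons - 1:
                p += int(intron_lens[i])
        gene_id = f"G{gi + 1:04d}"
        tx = Transcript(id=f"{gene_id}.1", gene_id=gene_id, chrom=config.chrom,
                        strand=strand, exons=tuple(exons))
        gene = Gene(id=gene_id, chrom=config.chrom, strand=strand)
        gene.add_transcript(tx)
        gene.representative = tx.id
        gene_set.add_gene(gene)
        pos = p + config.gene_spacing
    length = config.chrom_length if config.chrom_length is not None else max(pos, 1000)
    if pos > length:
        raise ValueError(
            f"genes require {pos} bp but chrom_length is {length}; "
            f"increase chrom_length or reduce n_genes"
        )
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    return seq, gene_set


def write_fasta(seq: str, path: str, chrom: str = "chr1", width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

def _simulate_gene_molecules(layout: _GeneLayout, config: SimConfig,
                             rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fractions, pol_positions, states[n, k]) for one gene."""
    n = config.molecules_per_gene
    k = layout.k
    lam = config.maturation_length
    c = config.cooperativity
    frac = rng.choice(3, size=n, p=config.mix_weights)
    pol = np.full(n, layout.pre_len, dtype=np.int64)
    is_rnae = frac == 1
    if is_rnae.any():
        pol[is_rnae] = rng.integers(1, layout.pre_len + 1, int(is_rnae.sum()))
    states = np.zeros((n, k), dtype=np.int8)
    for i in range(k):
        # cooperativity from the already-decided 5' neighbour
        nb = (states[:, i - 1] == SPLICED).astype(float) if i > 0 else np.zeros(n)
        u = rng.random(n)
        # RNAe: distance-dependent splicing, only for fully transcribed introns
        transcribed = pol >= layout.t_end[i]
        d = np.maximum(pol - layout.t_end[i], 0).astype(float)
        p_splice = 1.0 - np.exp(-d * c ** nb / lam)
        st_rnae = np.where(transcribed, np.where(u < p_splice, SPLICED, RETAINED),
                           NOT_YET).astype(np.int8)
        states[is_rnae, i] = st_rnae[is_rnae]
        # RNAf: flat retention probability, reduced by a spliced neighbour
        is_rnaf = frac == 2
        p_ret = config.rnaf_retention * c ** (-nb)
        states[is_rnaf, i] = (u < p_ret).astype(np.int8)[is_rnaf]
        # mRNA stays SPLICED
    return frac, pol, states


def simulate_molecules(gene_set: GeneSet, config: SimConfig,
                       rng: Optional[np.random.Generator] = None) -> Tuple[List[TranscriptMolecule], SimTruth]:
    """Draw molecules for every gene; returns them plus the ground truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    layouts = {g.id: _GeneLayout(g) for g in gene_set}
    molecules: List[TranscriptMolecule] = []
    for gene in gene_set:
        layout = layouts[gene.id]
        frac, pol, states = _simulate_gene_molecules(layout, config, rng)
        for m in range(len(frac)):
            molecules.append(TranscriptMolecule(
                gene_id=gene.id,
                fraction=_FRACTIONS[frac[m]],
                pol_position=int(pol[m]),
                splice_state=tuple(int(s) for s in states[m]),
            ))
    return molecules, SimTruth(layouts, molecules)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _molecule_segments(layout: _GeneLayout, pol: int,
                       states: Sequence[int]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(m_start, p_start, length) arrays of retained pre-mRNA pieces."""
    m_starts, p_starts, lengths = [], [], []
    m = 0
    for p_lo, p_hi, intron_idx in layout.features:
        if intron_idx >= 0 and states[intron_idx] == SPLICED:
            continue
        hi = min(p_hi, pol)
        if hi <= p_lo:
            if p_lo >= pol:
                break
            continue
        m_starts.append(m)
        p_starts.append(p_lo)
        lengths.append(hi - p_lo)
        m += hi - p_lo
    return (np.array(m_starts, dtype=np.int64),
            np.array(p_starts, dtype=np.int64),
            np.array(lengths, dtype=np.int64))


def _lift_reads(layout: _GeneLayout, seg_m: np.ndarray, seg_p: np.ndarray,
                seg_len: np.ndarray, starts: np.ndarray,
                lengths: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map molecule-coordinate reads to genomic blocks.

    Returns (block_start, block_end, local_read_idx) with per-read blocks
    merged across pre-mRNA-contiguous segments and sorted by genomic start
    within each read.
    """
    a = starts[:, None]  # (k, 1)
    b = (starts + lengths)[:, None]
    seg_lo = seg_m[None, :]
    seg_hi = (seg_m + seg_len)[None, :]
    ov_lo = np.maximum(a, seg_lo)
    ov_hi = np.minimum(b, seg_hi)
    valid = ov_hi > ov_lo
    ridx, sidx = np.nonzero(valid)
    plen = (ov_hi - ov_lo)[ridx, sidx]
    p_lo = seg_p[sidx] + (ov_lo[ridx, sidx] - seg_m[sidx])
    if layout.strand == "+":
        g_lo = layout.g_start + p_lo
        g_hi = g_lo + plen
    else:
        g_hi = layout.g_end - p_lo
        g_lo = g_hi - plen
        # blocks of one read come out in decreasing genomic order: reverse
        order = np.lexsort((g_lo, ridx))
        ridx, g_lo, g_hi = ridx[order], g_lo[order], g_hi[order]
    # merge genomically adjacent blocks of the same read (exon|retained-intron
    # junctions are contiguous on the genome)
    if len(ridx) > 1:
        same = (ridx[1:] == ridx[:-1]) & (g_lo[1:] == g_hi[:-1])
        keep_start = np.concatenate([[True], ~same])
        group = np.cumsum(keep_start) - 1
        out_lo = g_lo[keep_start]
        out_hi = np.zeros(group.max() + 1, dtype=np.int64)
        np.maximum.at(out_hi, group, g_hi)
        out_r = ridx[keep_start]
        return out_lo, out_hi, out_r
    return g_lo, g_hi, ridx


def simulate_reads(
    gene_set: GeneSet,
    molecules: List[TranscriptMolecule],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[SimTruth] = None,
    sam_path: Optional[str] = None,
    genome: Optional[str] = None,
) -> Tuple[ReadBlocks, SimTruth]:
    """Fragment the molecules into aligned reads.

    Each molecule emits a Poisson number of ``read_length`` fragments whose
    positions are uniform over the molecule including both ends (fragments
    are clipped where they run off the molecule, mimicking end fragments of
    random fragmentation; mRNA positions are optionally skewed 3'-ward by
    ``three_prime_bias``).  End-clipping makes the expected coverage of
    *every* base of *every* molecule identical (``read_length`` start
    positions each), which is what makes the splice-site ratio an unbiased
    estimator of the molecule-level unspliced fraction: without it, junctions
    close to a molecule end — systematically the recently transcribed,
    unspliced ones — would be under-sampled.  Molecules shorter than the
    read length are skipped and counted.  When ``sam_path`` is given
    a coordinate-sorted SAM/BAM with proper N-skip CIGARs is written
    (sequence taken from ``genome`` when provided).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    layouts = {g.id: _GeneLayout(g) for g in gene_set}
    if truth is None:
        truth = SimTruth(layouts, molecules)
    rl = config.read_length
    rate = config.depth / (config.molecules_per_gene * rl)
    all_lo, all_hi, all_read = [], [], []
    read_strand: List[int] = []
    n_reads = 0
    n_short = 0
    beta = config.three_prime_bias
    for mol in molecules:
        layout = layouts[mol.gene_id]
        seg_m, seg_p, seg_len = _molecule_segments(layout, mol.pol_position,
                                                   mol.splice_state)
        mol_len = int(seg_len.sum())
        if mol_len < rl:
            n_short += 1
            continue
        n_positions = mol_len + rl - 1
        k = rng.poisson(n_positions * rate)
        if k == 0:
            continue
        u = rng.random(k)
        if mol.fraction == "mRNA" and beta > 0:
            u = u ** (1.0 / (1.0 + beta))  # skew toward the 3' end
        pos = np.minimum((u * n_positions).astype(np.int64), n_positions - 1) - (rl - 1)
        starts = np.maximum(pos, 0)
        lengths = np.minimum(pos + rl, mol_len) - starts
        g_lo, g_hi, ridx = _lift_reads(layout, seg_m, seg_p, seg_len, starts, lengths)
        all_lo.append(g_lo)
        all_hi.append(g_hi)
        all_read.append(ridx + n_reads)
        read_strand.extend([1 if layout.strand == "+" else -1] * k)
        n_reads += k
    truth.n_short_skipped = n_short
    if all_lo:
        lo = np.concatenate(all_lo)
        hi = np.concatenate(all_hi)
        ridx = np.concatenate(all_read)
    else:
        lo = hi = ridx = np.zeros(0, dtype=np.int64)
    strand_per_read = np.array(read_strand, dtype=np.int8)
    chrom = next(iter(gene_set)).chrom if len(gene_set) else config.chrom
    blocks = ReadBlocks.from_arrays(
        chrom, lo, hi, ridx,
        strand_per_read[ridx] if len(ridx) else np.zeros(0, dtype=np.int8),
    )
    blocks.n_reads = n_reads
    blocks.n_fragments = n_reads
    if sam_path is not None:
        _write_sam(sam_path, chrom, lo, hi, ridx, strand_per_read, config, genome)
    return blocks, truth


def _write_sam(path: str, chrom: str, lo: np.ndarray, hi: np.ndarray,
               ridx: np.ndarray, strand_per_read: np.ndarray,
               config: SimConfig, genome: Optional[str]) -> None:
    """Write reads as a coordinate-sorted SAM (or BAM + index)."""
    chrom_len = (len(genome) if genome is not None
                 else (int(hi.max()) + config.gene_spacing if len(hi) else 1000))
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_len}]}
    # gather blocks per read
    per_read: Dict[int, List[Tuple[int, int]]] = {}
    for s, e, r in zip(lo.tolist(), hi.tolist(), ridx.tolist()):
        per_read.setdefault(r, []).append((s, e))
    records = []
    for r, bl in per_read.items():
        bl.sort()
        records.append((bl[0][0], r, bl))
    records.sort()
    is_bam = path.endswith(".bam")
    with pysam.AlignmentFile(path, "wb" if is_bam else "w", header=header) as out:
        for pos, r, bl in records:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"sim{r}"
            rec.flag = 16 if strand_per_read[r] < 0 else 0
            rec.reference_id = 0
            rec.reference_start = pos
            rec.mapping_quality = 60
            cig = []
            for j, (s, e) in enumerate(bl):
                if j:
                    cig.append((3, s - bl[j - 1][1]))  # N skip
                cig.append((0, e - s))  # M
            rec.cigartuples = cig
            if genome is not None:
                rec.query_sequence = "".join(genome[s:e] for s, e in bl)
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * sum(e - s for s, e in bl))
            rec.set_tag("NH", 1)
            out.write(rec)
    if is_bam:
        pysam.index(path)


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genome: str
    gene_set: GeneSet
    reads: ReadBlocks
    truth: SimTruth


def simulate_dataset(config: SimConfig, out_dir: Optional[str] = None,
                     write_bam: bool = False) -> SimResult:
    """Genome + gene models + molecules + reads in one deterministic call.

    With ``out_dir`` set, writes genome.fa, genes.gtf, reads.sam (or .bam
    with index), truth.tsv and a config echo (config.json).
    """
    rng = np.random.default_rng(config.seed)
    genome, gene_set = simulate_genome(config, rng)
    molecules, truth = simulate_molecules(gene_set, config, rng)
    sam_path = None
    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        write_fasta(genome, f"{out_dir}/genome.fa", chrom=config.chrom)
        gene_set.write_gtf(f"{out_dir}/genes.gtf")
        sam_path = f"{out_dir}/reads.bam" if write_bam else f"{out_dir}/reads.sam"
    reads, truth = simulate_reads(gene_set, molecules, config, rng, truth=truth,
                                  sam_path=sam_path, genome=genome)
    if out_dir is not None:
        truth.table(gene_set).to_csv(f"{out_dir}/truth.tsv", sep="\t", index=False)
        with open(f"{out_dir}/config.json", "w") as fh:
            json.dump(asdict(config), fh, indent=2, default=str)
    return SimResult(config, genome, gene_set, reads, truth)
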