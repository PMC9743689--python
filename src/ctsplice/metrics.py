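"""Co-transcriptional splicing statistics from boundary read counts.

The central quantity is the splice-site ratio.  At each intron boundary the
coverage of the first (5'SS) or last (3'SS) intronic base is divided by the
coverage of the single adjacent exonic base:

    5'SS ratio = reads covering first intronic base / reads covering last
                 upstream-exon base
    3'SS ratio = reads covering last intronic base / reads covering first
                 downstream-exon base

Reads spliced across the intron (an N skip) cover only the exonic side, so
the ratio estimates the unspliced (intron-retaining) fraction of molecules at
that junction: 0 = fully spliced, 1 = fully retained; it is therefore
*negatively* correlated with splicing efficiency.  Single-base adjacency makes
the numerator (apart from reads ending exactly at the boundary) a subset of
the denominator, so the estimator behaves binomially.  An optional window
averages coverage over N flanking bases on each side for robustness.

Gene-level aggregation follows the standard recipe: the representative
transcript defines the intron set, genes are kept when FPKM >= 1, and the
gene's ratio is the unweighted mean of its defined per-intron ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .alignments import AlignedRead, ReadBlocks, _as_blocks
from .annotation import GeneSet, Gene, Intron

__all__ = [
    "JunctionCounts",
    "SSRatio",
    "count_boundary_reads",
    "junction_counts_table",
    "ss_ratio",
    "compute_fpkm",
    "filter_expressed",
    "gene_ss_ratio",
    "intron_exon_ratio",
    "summarize_genes",
    "stratify_by_intron_order",
    "stratify_by_intron_number",
    "compare_fractions",
    "CompareResult",
    "qpcr_unspliced_spliced_ratio",
]


@dataclass(frozen=True)
class JunctionCounts:
    """Boundary read evidence at one intron (window-averaged, so float)."""

    intron: Intron
    intronic_5p: float
    exonic_5p: float
    intronic_3p: float
    exonic_3p: float

    def __post_init__(self) -> None:
        for v in (self.intronic_5p, self.exonic_5p, self.intronic_3p, self.exonic_3p):
            if v < 0:
                raise ValueError("boundary counts must be >= 0")


@dataclass(frozen=True)
class SSRatio:
    side: str  # '5p' or '3p'
    numerator: float
    denominator: float

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float:
        """intronic/exonic; NaN when the exonic denominator is zero."""
        return self.numerator / self.denominator if self.defined else math.nan


def _strand_arg(policy: str, gene_strand: str) -> Optional[str]:
    if policy == "unstranded":
        return None
    if policy == "sense":
        return gene_strand
    if policy == "antisense":
        return "-" if gene_strand == "+" else "+"
    raise ValueError(f"invalid strand policy {policy!r}")


def _boundary_positions(intron: Intron, window: int) -> np.ndarray:
    """4*window genomic positions: intronic_5p, exonic_5p, intronic_3p,
    exonic_3p windows, each extending away from the boundary."""
    s, e, w = intron.start, intron.end, window
    if intron.strand == "+":
        i5 = np.arange(s, s + w)
        e5 = np.arange(s - w, s)
        i3 = np.arange(e - w, e)
        e3 = np.arange(e, e + w)
    else:
        i5 = np.arange(e - w, e)
        e5 = np.arange(e, e + w)
        i3 = np.arange(s, s + w)
        e3 = np.arange(s - w, s)
    return np.concatenate([i5, e5, i3, e3])


def count_boundary_reads(
    reads: Union[ReadBlocks, Iterable[AlignedRead]],
    intron: Intron,
    window: int = 1,
    strand_policy: str = "unstranded",
) -> JunctionCounts:
    """Coverage at the four boundary positions of one intron.

    With ``window`` > 1 the count is the mean coverage over that many flanking
    bases on each side of each splice site.  A read spliced across the intron
    contributes to exonic counts only, because the N skip removes the intronic
    bases from its aligned blocks.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if intron.length < window:
        window = intron.length
    blocks = _as_blocks(reads)
    pos = _boundary_positions(intron, window)
    cov = blocks.coverage_at(
        intron.chrom, pos, strand=_strand_arg(strand_policy, intron.strand)
    ).astype(float)
    parts = cov.reshape(4, window).mean(axis=1)
    return JunctionCounts(intron, parts[0], parts[1], parts[2], parts[3])


def junction_counts_table(
    reads: Union[ReadBlocks, Iterable[AlignedRead]],
    introns: Sequence[Intron],
    window: int = 1,
    strand_policy: str = "unstranded",
) -> pd.DataFrame:
    """Vectorised boundary counting over many introns.

    Returns one row per intron with the four window-averaged counts and the
    two splice-site ratios (NaN where the exonic denominator is zero).
    """
    blocks = _as_blocks(reads)
    rows = []
    # group by (chrom, strand-policy arg) so each group is one array query
    for intron in introns:
        w = min(window, intron.length)
        pos = _boundary_positions(intron, w)
        cov = blocks.coverage_at(
            intron.chrom, pos, strand=_strand_arg(strand_policy, intron.strand)
        ).astype(float)
        i5, e5, i3, e3 = cov.reshape(4, w).mean(axis=1)
        rows.append(
            {
                "gene": intron.gene_id,
                "chrom": intron.chrom,
                "strand": intron.strand,
                "order": intron.order,
                "start": intron.start,
                "end": intron.end,
                "intronic_5p": i5,
                "exonic_5p": e5,
                "intronic_3p": i3,
                "exonic_3p": e3,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "chrom", "strand", "order", "start", "end",
                 "intronic_5p", "exonic_5p", "intronic_3p", "exonic_3p"],
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["ratio_5p"] = np.where(
            table["exonic_5p"] > 0, table["intronic_5p"] / table["exonic_5p"], np.nan
        )
        table["ratio_3p"] = np.where(
            table["exonic_3p"] > 0, table["intronic_3p"] / table["exonic_3p"], np.nan
        )
    return table


def ss_ratio(counts: JunctionCounts, side: str) -> SSRatio:
    """Splice-site ratio for one side; undefined (NaN) when exonic count is 0."""
    if side == "5p":
        return SSRatio("5p", counts.intronic_5p, counts.exonic_5p)
    if side == "3p":
        return SSRatio("3p", counts.intronic_3p, counts.exonic_3p)
    raise ValueError(f"side must be '5p' or '3p', got {side!r}")


def compute_fpkm(
    fragment_count: float, exonic_length: int, total_mapped_fragments: int
) -> float:
    """Fragments per kilobase of exon model per million mapped fragments."""
    if exonic_length <= 0:
        raise ValueError("exonic_length must be > 0")
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be > 0")
    return fragment_count * 1e9 / (exonic_length * total_mapped_fragments)


def filter_expressed(summaries: pd.DataFrame, fpkm_min: float = 1.0) -> pd.DataFrame:
    """Keep genes with FPKM >= ``fpkm_min`` (boundary inclusive), order kept."""
    return summaries[summaries["fpkm"] >= fpkm_min]


def gene_ss_ratio(ratios_5p: Sequence[float], ratios_3p: Sequence[float]) -> tuple:
    """Unweighted mean over defined (non-NaN) per-intron ratios, per side.

    NaN when no intron on that side has a defined ratio: an undefined ratio
    carries no information and is skipped, not imputed.
    """
    def _mean(vals: Sequence[float]) -> float:
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[~np.isnan(arr)]
        return float(arr.mean()) if len(arr) else math.nan

    return _mean(ratios_5p), _mean(ratios_3p)


def _count_fragments(blocks: ReadBlocks, gene: Gene) -> int:
    """Distinct fragments with >= 1 bp overlap of the representative exons."""
    tx = gene.representative_transcript
    frags: set = set()
    for s, e in tx.exons:
        _, _, _, _, frag = blocks.overlapping(gene.chrom, s, e)
        frags.update(frag.tolist())
    return len(frags)


def intron_exon_ratio(
    gene: Gene, reads: Union[ReadBlocks, Iterable[AlignedRead]]
) -> float:
    """Length-normalised intronic over exonic depth for one gene.

    (summed intronic coverage / intronic length) divided by (summed exonic
    coverage / exonic length) over the representative transcript; NaN when
    exonic coverage is zero.
    """
    blocks = _as_blocks(reads)
    tx = gene.representative_transcript
    span_s, span_e = tx.span
    cov = blocks.pileup(gene.chrom, span_s, span_e)
    exon_mask = np.zeros(span_e - span_s, dtype=bool)
    for s, e in tx.exons:
        exon_mask[s - span_s:e - span_s] = True
    exon_len = int(exon_mask.sum())
    intron_len = len(exon_mask) - exon_len
    if intron_len == 0:
        raise ValueError(f"gene {gene.id}: no introns")
    exon_depth = cov[exon_mask].sum() / exon_len
    if exon_depth == 0:
        return math.nan
    intron_depth = cov[~exon_mask].sum() / intron_len
    return float(intron_depth / exon_depth)


def summarize_genes(
    gene_set: GeneSet,
    reads: Union[ReadBlocks, Iterable[AlignedRead]],
    window: int = 1,
    strand_policy: str = "unstranded",
    total_mapped_fragments: Optional[int] = None,
    fpkm_min: Optional[float] = 1.0,
    with_intron_exon_ratio: bool = False,
) -> tuple:
    """Per-intron and per-gene splicing summaries for one library.

    Returns ``(per_intron, per_gene)`` DataFrames.  ``per_gene`` carries FPKM
    (fragments over representative exons, library total as denominator),
    intron count, and the mean 5'/3' splice-site ratios over defined introns.
    When ``fpkm_min`` is not None the expression filter is applied to *both*
    tables (introns of dropped genes are excluded from downstream statistics).
    """
    blocks = _as_blocks(reads)
    introns = list(gene_set.representative_introns())
    per_intron = junction_counts_table(
        blocks, introns, window=window, strand_policy=strand_policy
    )
    total = total_mapped_fragments or blocks.n_fragments
    gene_rows = []
    for gene in gene_set:
        tx = gene.representative_transcript
        n_introns = len(tx.exons) - 1
        if n_introns == 0:
            continue
        sub = per_intron[per_intron["gene"] == gene.id]
        mean_5p, mean_3p = gene_ss_ratio(sub["ratio_5p"], sub["ratio_3p"])
        frags = _count_fragments(blocks, gene)
        fpkm = compute_fpkm(frags, tx.spliced_length, total) if total else math.nan
        row = {
            "gene": gene.id,
            "fpkm": fpkm,
            "n_introns": n_introns,
            "fragment_count": frags,
            "exonic_length": tx.spliced_length,
            "mean_5p": mean_5p,
            "mean_3p": mean_3p,
        }
        if with_intron_exon_ratio:
            row["intron_exon_ratio"] = intron_exon_ratio(gene, blocks)
        gene_rows.append(row)
    per_gene = pd.DataFrame(gene_rows)
    if fpkm_min is not None and len(per_gene):
        per_gene = filter_expressed(per_gene, fpkm_min)
        per_intron = per_intron[per_intron["gene"].isin(per_gene["gene"])]
    return per_intron, per_gene


def _quantile_row(values: np.ndarray) -> dict:
    values = values[~np.isnan(values)]
    if not len(values):
        return {"n": 0, "median": math.nan, "q25": math.nan, "q75": math.nan}
    return {
        "n": int(len(values)),
        "median": float(np.median(values)),
        "q25": float(np.percentile(values, 25)),
        "q75": float(np.percentile(values, 75)),
    }


def stratify_by_intron_order(
    per_intron: pd.DataFrame, per_gene: pd.DataFrame, k: int
) -> pd.DataFrame:
    """Distribution of per-intron ratios at each intron order 1..k, over the
    genes that have exactly ``k`` introns (expression filter applied upstream).
    """
    genes_k = per_gene.loc[per_gene["n_introns"] == k, "gene"]
    sub = per_intron[per_intron["gene"].isin(genes_k)]
    rows = []
    for order in range(1, k + 1):
        at_order = sub[sub["order"] == order]
        row = {"order": order}
        for side in ("5p", "3p"):
            q = _quantile_row(at_order[f"ratio_{side}"].to_numpy(dtype=float))
            row.update({f"{key}_{side}": val for key, val in q.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_by_intron_number(
    per_gene: pd.DataFrame, k_range: Iterable[int] = range(1, 11)
) -> pd.DataFrame:
    """Distribution of gene-mean ratios per intron-count class.

    Empty classes are reported with n = 0 and NaN quantiles.
    """
    rows = []
    for k in k_range:
        sub = per_gene[per_gene["n_introns"] == k]
        row = {"n_introns": k}
        for side in ("5p", "3p"):
            q = _quantile_row(sub[f"mean_{side}"].to_numpy(dtype=float))
            row.update({f"{key}_{side}": val for key, val in q.items()})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CompareResult:
    statistic: float  # Mann-Whitney U of the first sample
    pvalue: float
    method: str  # 'exact' or 'asymptotic'


def compare_fractions(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> CompareResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test between two ratio collections.

    Exact enumeration when the combined sample size is <= 20 and there are no
    ties; normal approximation with tie correction otherwise.  If every pooled
    value is identical the test is degenerate and p = 1.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2.0
        return CompareResult(u, 1.0, "degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return CompareResult(float(res.statistic), float(res.pvalue), method)


def qpcr_unspliced_spliced_ratio(
    ct_unspliced: float, ct_spliced: float, efficiency: float = 2.0
) -> float:
    """Unspliced/spliced abundance ratio from qPCR Ct values.

    ratio = efficiency ** (ct_spliced - ct_unspliced); a *lower* Ct for the
    unspliced amplicon means more unspliced template.
    """
    if not (math.isfinite(ct_unspliced) and math.isfinite(ct_spliced)):
        raise ValueError("Ct values must be finite")
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    return efficiency ** (ct_spliced - ct_unspliced)
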