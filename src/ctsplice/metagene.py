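"""Windowed TPM coverage tracks and scaled TSS->PAS metagene profiles.

A chromatin-bound RNA library is dominated by elongating transcripts
truncated at the polymerase position, so its coverage declines from the
transcription start site (TSS) to the polyadenylation site (PAS); a mature
mRNA library is flat (or mildly 3'-biased).  The metagene profile makes that
contrast a single number: the Spearman correlation of bin index against bin
mean, negative for a 5'->3' decline.

Tracks are per-base coverage averaged in non-overlapping windows (default
5 bp, tiled, stride = window size) and scaled by 1e6 / total aligned bases,
so the genome-wide sum of value x window-length is 1e6 regardless of library
size.  Profiles rescale each gene body (TSS to PAS, strand-aware) onto a
fixed number of bins and average across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, NamedTuple, Optional, Union

import numpy as np
from scipy import stats

from .alignments import AlignedRead, ReadBlocks, _as_blocks
from .annotation import GeneSet

__all__ = [
    "WindowedTrack",
    "MetageneProfile",
    "SlopeResult",
    "windowed_tpm",
    "metagene_profile",
    "profile_slope",
    "write_bedgraph",
]


@dataclass
class WindowedTrack:
    chrom: str
    window_size: int
    values: np.ndarray  # TPM-scaled mean per-base coverage per window
    scale: float  # multiplicative constant applied to raw coverage

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def per_base(self, start: int, end: int) -> np.ndarray:
        """Window values expanded to per-base resolution over [start, end)."""
        idx = np.arange(start, end) // self.window_size
        return self.values[idx]


@dataclass
class MetageneProfile:
    n_bins: int
    bin_means: np.ndarray
    n_genes: int
    anchors: tuple = ("TSS", "PAS")


def windowed_tpm(
    reads: Union[ReadBlocks, Iterable[AlignedRead]],
    chrom_lengths: Dict[str, int],
    window_size: int = 5,
) -> Dict[str, WindowedTrack]:
    """Library-size-normalised windowed coverage, one track per chromosome.

    Each window holds the mean per-base read coverage scaled by
    ``1e6 / total_aligned_bases`` (an empty library yields all-zero tracks
    with scale 0).  The genome-wide sum of value x window-length is therefore
    1e6, making tracks invariant under uniform read duplication.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    blocks = _as_blocks(reads)
    total = blocks.total_aligned_bases()
    scale = 1e6 / total if total else 0.0
    tracks = {}
    for chrom, length in chrom_lengths.items():
        n_win = math.ceil(length / window_size)
        if blocks.n_blocks(chrom):
            cov = blocks.pileup(chrom, 0, length).astype(float)
        else:
            cov = np.zeros(length)
        padded = np.zeros(n_win * window_size)
        padded[:length] = cov
        win_means = padded.reshape(n_win, window_size).mean(axis=1)
        # last, partial window: mean over real bases only
        rem = length % window_size
        if rem:
            win_means[-1] = cov[length - rem:].mean()
        tracks[chrom] = WindowedTrack(chrom, window_size, win_means * scale, scale)
    return tracks


def metagene_profile(
    tracks: Dict[str, WindowedTrack],
    gene_set: GeneSet,
    n_bins: int = 100,
    min_gene_length: Optional[int] = None,
) -> MetageneProfile:
    """Average scaled coverage over gene bodies resampled to ``n_bins``.

    Each gene's TSS->PAS span (representative transcript, oriented in
    transcription direction) is cut into ``n_bins`` near-equal slices of
    per-base track values and each slice averaged; ``bin_means`` averages
    those per-gene profiles.  Genes shorter than ``min_gene_length`` (default
    10 x window size) are skipped; no qualifying gene is an error.
    """
    per_gene = []
    for gene in gene_set:
        track = tracks.get(gene.chrom)
        if track is None:
            continue
        if min_gene_length is None:
            min_len = 10 * track.window_size
        else:
            min_len = min_gene_length
        start, end = gene.representative_transcript.span
        if end - start < max(min_len, n_bins):
            continue
        values = track.per_base(start, end)
        if gene.strand == "-":
            values = values[::-1]
        binned = np.array([chunk.mean() for chunk in np.array_split(values, n_bins)])
        per_gene.append(binned)
    if not per_gene:
        raise ValueError("no gene passed the length filter for the metagene profile")
    return MetageneProfile(
        n_bins=n_bins,
        bin_means=np.mean(per_gene, axis=0),
        n_genes=len(per_gene),
    )


class SlopeResult(NamedTuple):
    rho: float  # Spearman correlation of bin index vs bin mean
    degenerate: bool  # True when the profile is constant

    def __float__(self) -> float:
        return self.rho


def profile_slope(profile: MetageneProfile) -> SlopeResult:
    """Spearman rank correlation of bin index against bin mean.

    Negative values indicate a 5'->3' coverage decline.  A constant profile
    has no defined rank correlation and is reported as 0 with the degenerate
    flag set.
    """
    if profile.n_bins < 3:
        raise ValueError("need at least 3 bins")
    means = profile.bin_means
    if np.all(means == means[0]):
        return SlopeResult(0.0, True)
    rho, _ = stats.spearmanr(np.arange(profile.n_bins), means)
    return SlopeResult(float(rho), False)


def write_bedgraph(track: WindowedTrack, path: str, mode: str = "w") -> None:
    """Write a windowed track as bedGraph (0-based half-open intervals)."""
    w = track.window_size
    with open(path, mode) as fh:
        for i, v in enumerate(track.values):
            if v:
                fh.write(f"{track.chrom}\t{i * w}\t{(i + 1) * w}\t{v:.6g}\n")


def plot_profile(profiles: Dict[str, MetageneProfile], path: str) -> None:
    """Minimal metagene figure: one line per labelled profile, TSS to PAS."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, profile in profiles.items():
        x = np.linspace(0, 1, profile.n_bins)
        ax.plot(x, profile.bin_means, label=label)
    ax.set_xticks([0, 1])
    ax.set_xticklabels(["TSS", "PAS"])
    ax.set_ylabel("mean scaled coverage")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
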