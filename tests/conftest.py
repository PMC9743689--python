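"""Shared fixtures: tiny hand-built gene models and SAM writers."""

import numpy as np
import pysam
import pytest

from ctsplice import Gene, GeneSet, Transcript


def make_gene(gene_id, strand, exons, chrom="chr1", tx_suffix=".1"):
    gene = Gene(id=gene_id, chrom=chrom, strand=strand)
    tx = Transcript(id=gene_id + tx_suffix, gene_id=gene_id, chrom=chrom,
                    strand=strand, exons=tuple(exons))
    gene.add_transcript(tx)
    gene.representative = tx.id
    return gene


@pytest.fixture
def toy_gene_set():
    """Two genes on opposite strands with 2 and 3 exons."""
    gs = GeneSet()
    gs.add_gene(make_gene("GA", "+", [(100, 200), (300, 400)]))
    gs.add_gene(make_gene("GB", "-", [(1000, 1100), (1200, 1300), (1400, 1500)]))
    return gs


@pytest.fixture
def sam_writer(tmp_path):
    """Write a SAM file from (qname, flag, pos, cigar[, extras]) tuples."""

    def _write(records, chrom="chr1", length=100_000, name="reads.sam"):
        path = str(tmp_path / name)
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for entry in records:
                qname, flag, pos, cigar = entry[:4]
                extras = entry[4] if len(entry) > 4 else {}
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = qname
                rec.flag = flag
                rec.reference_id = 0
                rec.reference_start = pos
                rec.mapping_quality = extras.get("mapq", 60)
                rec.cigarstring = cigar
                for tag, val in extras.get("tags", {}).items():
                    rec.set_tag(tag, val)
                out.write(rec)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
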