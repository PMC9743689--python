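"""Simulator: determinism, structural bounds, limits, lift-over, ground truth."""

import dataclasses
import math

import numpy as np
import pysam
import pytest

from ctsplice import (
    ReadBlocks,
    SimConfig,
    load_alignments,
    simulate_dataset,
    simulate_genome,
    simulate_molecules,
    simulate_reads,
    true_retention,
)
from ctsplice.simulate import (
    NOT_YET,
    RETAINED,
    SPLICED,
    SimTruth,
    TranscriptMolecule,
    _GeneLayout,
)

SMALL = SimConfig(n_genes=6, depth=30, molecules_per_gene=80, seed=5)

RNAE_ONLY = {"mRNA": 0.0, "RNAe": 1.0, "RNAf": 0.0}
MRNA_ONLY = {"mRNA": 1.0, "RNAe": 0.0, "RNAf": 0.0}
RNAF_ONLY = {"mRNA": 0.0, "RNAe": 0.0, "RNAf": 1.0}


class TestConfig:
    def test_mix_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(fraction_mix={"mRNA": 0.5, "RNAe": 0.2, "RNAf": 0.2})

    def test_retention_probability_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(rnaf_retention=1.5)


class TestGenome:
    def test_zero_genes_still_valid_fasta(self, tmp_path):
        genome, gs = simulate_genome(SimConfig(n_genes=0))
        assert len(gs) == 0
        assert len(genome) >= 1000
        assert set(genome) <= set("ACGT")

    def test_same_seed_gives_identical_gtf_bytes(self, tmp_path):
        for name in ("a", "b"):
            _, gs = simulate_genome(SMALL)
            gs.write_gtf(str(tmp_path / f"{name}.gtf"))
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()

    def test_exon_count_range_bounds_introns(self):
        _, gs = simulate_genome(SimConfig(n_genes=50, exon_count_range=(2, 10), seed=1))
        intron_counts = {len(g.representative_transcript.introns) for g in gs}
        assert intron_counts <= set(range(1, 10))
        assert len(gs) == 50

    def test_genes_do_not_overlap(self):
        _, gs = simulate_genome(SimConfig(n_genes=30, seed=3))
        spans = sorted(g.span for g in gs)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 <= s1

    def test_fixed_chrom_length_too_small_is_error(self):
        with pytest.raises(ValueError, match="chrom_length"):
            simulate_genome(SimConfig(n_genes=30, chrom_length=2000))


class TestMolecules:
    def test_mrna_only_is_fully_spliced(self):
        cfg = dataclasses.replace(SMALL, fraction_mix=MRNA_ONLY)
        _, gs = simulate_genome(cfg)
        molecules, _ = simulate_molecules(gs, cfg)
        assert all(set(m.splice_state) <= {SPLICED} for m in molecules)
        assert all(m.fraction == "mRNA" for m in molecules)

    def test_tiny_maturation_length_splices_every_transcribed_intron(self):
        """lambda -> 0: splicing is instantaneous once the 3'SS is made."""
        cfg = dataclasses.replace(SMALL, fraction_mix=RNAE_ONLY,
                                  maturation_length=1e-9)
        _, gs = simulate_genome(cfg)
        molecules, _ = simulate_molecules(gs, cfg)
        layouts = {g.id: _GeneLayout(g) for g in gs}
        for m in molecules:
            lay = layouts[m.gene_id]
            for i, state in enumerate(m.splice_state):
                if m.pol_position > lay.t_end[i]:
                    assert state == SPLICED
                elif m.pol_position == lay.t_end[i]:
                    # just transcribed: zero travel, so not yet spliced
                    assert state == RETAINED
                else:
                    assert state == NOT_YET

    def test_rnaf_retention_one_retains_everything(self):
        cfg = dataclasses.replace(SMALL, fraction_mix=RNAF_ONLY, rnaf_retention=1.0)
        _, gs = simulate_genome(cfg)
        molecules, _ = simulate_molecules(gs, cfg)
        assert all(set(m.splice_state) == {RETAINED} for m in molecules if m.splice_state)

    def test_large_lambda_matches_numerical_expectation(self):
        """Mean retention at a junction matches the exact average of
        1 - (1 - exp(-d/lambda)) over all equally likely polymerase
        positions (cooperativity off so introns are independent)."""
        cfg = SimConfig(n_genes=1, exon_count_range=(3, 3), seed=9,
                        molecules_per_gene=20000, fraction_mix=RNAE_ONLY,
                        maturation_length=50_000.0, cooperativity=1.0)
        _, gs = simulate_genome(cfg)
        molecules, truth = simulate_molecules(gs, cfg)
        gene = next(iter(gs))
        layout = _GeneLayout(gene)
        for iv in gene.representative_transcript.introns:
            i = iv.order - 1
            t_end = int(layout.t_end[i])
            # numerator: molecules containing the last intronic base and
            # retained (pol >= t_end; retention prob exp(-d/lambda));
            # denominator: molecules containing the downstream exonic base
            # (pol >= t_end + 1) -- the sets the ratio actually samples
            pols = np.arange(1, layout.pre_len + 1)
            p_ret = np.where(pols >= t_end,
                             np.exp(-np.maximum(pols - t_end, 0)
                                    / cfg.maturation_length), 0.0)
            expected = p_ret.sum() / np.sum(pols >= t_end + 1)
            observed, n_cov = truth.retention(iv, "3p")
            p = min(expected, 1.0)
            se = math.sqrt(p * (1 - p) / n_cov)
            assert abs(observed - expected) < 4 * se + 2e-3


class TestReads:
    def test_read_inside_retained_intron_is_single_block(self):
        cfg = dataclasses.replace(SMALL, fraction_mix=RNAF_ONLY, rnaf_retention=1.0,
                                  depth=60)
        res = simulate_dataset(cfg)
        for gene in res.gene_set:
            for iv in gene.representative_transcript.introns:
                if iv.length > cfg.read_length:
                    mid = (iv.start + iv.end) // 2
                    assert res.reads.coverage_at(gene.chrom, [mid])[0] > 0
                    return
        pytest.skip("no intron longer than a read in this fixture")

    def test_spliced_junction_reads_have_skip_of_intron_length(self, tmp_path):
        cfg = dataclasses.replace(SMALL, fraction_mix=MRNA_ONLY, depth=60)
        res = simulate_dataset(cfg, out_dir=str(tmp_path / "sim"))
        intron_lengths = {iv.length for g in res.gene_set
                          for iv in g.representative_transcript.introns}
        n_spliced = 0
        with pysam.AlignmentFile(str(tmp_path / "sim" / "reads.sam")) as fh:
            for rec in fh:
                skips = [n for op, n in rec.cigartuples if op == 3]
                for skip in skips:
                    assert skip in intron_lengths
                n_spliced += bool(skips)
        assert n_spliced > 0

    def test_same_seed_gives_identical_sam_bytes(self, tmp_path):
        for name in ("a", "b"):
            simulate_dataset(SMALL, out_dir=str(tmp_path / name))
        assert ((tmp_path / "a" / "reads.sam").read_bytes()
                == (tmp_path / "b" / "reads.sam").read_bytes())

    def test_sam_roundtrip_preserves_coverage(self, tmp_path):
        res = simulate_dataset(SMALL, out_dir=str(tmp_path / "sim"))
        reread = ReadBlocks.from_reads(
            load_alignments(str(tmp_path / "sim" / "reads.sam")))
        assert reread.n_reads == res.reads.n_reads
        for gene in res.gene_set:
            s, e = gene.span
            assert (res.reads.pileup(gene.chrom, s, e)
                    == reread.pileup(gene.chrom, s, e)).all()

    def test_liftover_roundtrip_identity(self):
        """Mapping each read's genomic blocks back through its gene layout
        must give one contiguous molecule interval of the read's length."""
        cfg = dataclasses.replace(SMALL, depth=40)
        rng = np.random.default_rng(cfg.seed)
        _, gs = simulate_genome(cfg, rng)
        molecules, truth = simulate_molecules(gs, cfg, rng)
        layouts = {g.id: _GeneLayout(g) for g in gs}
        # regenerate reads per molecule and invert them
        from ctsplice.simulate import _molecule_segments, _lift_reads
        rng2 = np.random.default_rng(1234)
        checked = 0
        for mol in molecules[:300]:
            lay = layouts[mol.gene_id]
            seg_m, seg_p, seg_len = _molecule_segments(lay, mol.pol_position,
                                                       mol.splice_state)
            mol_len = int(seg_len.sum())
            if mol_len < cfg.read_length:
                continue
            starts = rng2.integers(0, mol_len - cfg.read_length + 1, 3)
            lengths = np.full(3, cfg.read_length)
            g_lo, g_hi, ridx = _lift_reads(lay, seg_m, seg_p, seg_len,
                                           starts, lengths)
            # invert: genomic -> pre-mRNA -> molecule coordinate
            p_bounds = np.stack([seg_p, seg_p + seg_len], axis=1)
            for r in range(3):
                mol_positions = []
                for lo, hi in zip(g_lo[ridx == r], g_hi[ridx == r]):
                    if lay.strand == "+":
                        p0, p1 = lo - lay.g_start, hi - lay.g_start
                    else:
                        p0, p1 = lay.g_end - hi, lay.g_end - lo
                    for j, (ps, pe) in enumerate(p_bounds):
                        o0, o1 = max(p0, ps), min(p1, pe)
                        if o1 > o0:
                            m0 = seg_m[j] + (o0 - ps)
                            mol_positions.extend(range(m0, m0 + (o1 - o0)))
                mol_positions.sort()
                assert mol_positions == list(
                    range(starts[r], starts[r] + cfg.read_length))
                checked += 1
        assert checked >= 100


class TestTruth:
    def _truth_from_states(self, states, pol=None):
        """One '+' gene, exons (0,200),(300,500); one intron (200,300)."""
        from conftest import make_gene
        gene = make_gene("g", "+", [(0, 200), (300, 500)])
        layout = _GeneLayout(gene)
        mols = [TranscriptMolecule("g", "RNAf", p if p is not None else 500, (s,))
                for s, p in zip(states, pol or [None] * len(states))]
        return SimTruth({"g": layout}, mols), gene.representative_transcript.introns[0]

    def test_all_spliced_is_zero(self):
        truth, iv = self._truth_from_states([SPLICED] * 10)
        assert true_retention(truth, iv, "5p") == 0.0
        assert true_retention(truth, iv, "3p") == 0.0

    def test_all_retained_is_one(self):
        truth, iv = self._truth_from_states([RETAINED] * 10)
        assert true_retention(truth, iv, "5p") == 1.0
        assert true_retention(truth, iv, "3p") == 1.0

    def test_three_in_ten_counting(self):
        truth, iv = self._truth_from_states([RETAINED] * 3 + [SPLICED] * 7)
        assert true_retention(truth, iv, "5p") == pytest.approx(0.3)

    def test_unknown_intron_is_error(self):
        truth, _ = self._truth_from_states([SPLICED])
        from ctsplice.annotation import Intron
        stranger = Intron(gene_id="nope", chrom="chr1", strand="+",
                          order=1, start=5, end=10)
        with pytest.raises(KeyError):
            true_retention(truth, stranger)

    def test_truncated_molecules_not_counted_as_covering(self):
        # pol stops inside the first exon: molecule never reaches the junction
        truth, iv = self._truth_from_states([NOT_YET, RETAINED], pol=[100, 500])
        u5, n5 = truth.retention(iv, "5p")
        assert n5 == 1 and u5 == 1.0

    def test_short_molecules_are_skipped_and_logged(self):
        cfg = dataclasses.replace(SMALL, fraction_mix=RNAE_ONLY)
        rng = np.random.default_rng(cfg.seed)
        _, gs = simulate_genome(cfg, rng)
        molecules, truth = simulate_molecules(gs, cfg, rng)
        _, truth = simulate_reads(gs, molecules, cfg, rng, truth=truth)
        # uniform polymerase positions make sub-read-length molecules common
        assert truth.n_short_skipped > 0
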