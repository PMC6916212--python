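"""Sequence-level evolution: substitutions and indels."""

import numpy as np
import pytest

from splicesim.params import SimParams
from splicesim.sequence import (evolve_exon_sequence, evolve_gene_sequences,
                                evolve_intron_sequence, expected_indel_count)


class TestExpectedIndelCount:
    def test_exon_deletion_expectation(self):
        p = SimParams(k_indel=0.1)
        assert expected_indel_count(100, 0.2, p) * p.cd == pytest.approx(1.0)

    def test_intron_scaling(self):
        p = SimParams(k_indel=0.1, k_intron=1.5)
        lam = expected_indel_count(1000, 0.2, p, is_intron=True)
        assert lam * p.cd == pytest.approx(15.0)

    def test_zero_branch(self):
        assert expected_indel_count(100, 0.0, SimParams()) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            expected_indel_count(-5, 0.1, SimParams())


class TestExonEvolution:
    def test_zero_branch_identity(self, factory, small_models, rng):
        gene = factory.gene(["ATGAAACCCGGG"])
        exon = gene.exons()[0]
        before = exon.sequence
        evolve_exon_sequence(exon, 0.0, SimParams(), small_models, rng,
                             factory.ledger, factory.log)
        assert exon.sequence == before

    def test_substitution_count_poisson(self, factory, small_models, models):
        # with indels off, the substitution count is Poisson(n * t)
        rng = np.random.default_rng(61)
        n, t = 10_000, 0.5
        codons = models.codon_chain.generate_codons(n, rng)
        gene = factory.gene(["".join(codons)])
        exon = gene.exons()[0]
        params = SimParams(k_indel=0.0)
        evolve_exon_sequence(exon, t, params, small_models, rng,
                             factory.ledger, factory.log)
        subs = sum(1 for r in factory.log if r.type == "codon_sub")
        lam = n * t
        assert abs(subs - lam) < 3 * np.sqrt(lam)
        assert len(exon) == 3 * n  # no indels happened

    def test_substitutions_change_codons(self, factory, small_models, rng):
        gene = factory.gene(["ATGAAACCCGGGTTTAAA"])
        exon = gene.exons()[0]
        evolve_exon_sequence(exon, 2.0, SimParams(k_indel=0.0), small_models,
                             rng, factory.ledger, factory.log)
        for r in factory.log:
            if r.type == "codon_sub":
                assert r.payload["old"] != r.payload["new"]

    def test_frame_preserved_under_heavy_indels(self, factory, small_models):
        rng = np.random.default_rng(63)
        params = SimParams(k_indel=2.0)
        for _ in range(40):
            f = type(factory)()
            gene = f.gene(["ATGAAACCCGGG" * 4])
            exon = gene.exons()[0]
            evolve_exon_sequence(exon, 1.0, params, small_models, rng,
                                 f.ledger, f.log)
            assert len(exon) % 3 == 0 and len(exon) >= 3
            assert len(exon.seq) == len(exon.cols)

    def test_insertions_register_ledger_columns(self, factory, small_models):
        rng = np.random.default_rng(65)
        gene = factory.gene(["ATGAAACCCGGG"])
        exon = gene.exons()[0]
        params = SimParams(k_indel=3.0, ci=1.0, cd=0.0)
        evolve_exon_sequence(exon, 1.0, params, small_models, rng,
                             factory.ledger, factory.log)
        order = factory.ledger.linearize()
        pos = {c: i for i, c in enumerate(order)}
        ranks = [pos[c] for c in exon.cols]
        assert ranks == sorted(ranks)  # row order embeds in global order


class TestIntronEvolution:
    def _intron(self, factory, interior=40):
        gene = factory.gene(["AAA", "CCC"],
                            ["GT" + "A" * interior + "AG"])
        return gene, gene.introns()[0]

    def test_zero_branch_identity(self, factory, small_models, rng):
        _, intron = self._intron(factory)
        before = intron.sequence
        evolve_intron_sequence(intron, 0.0, SimParams(), small_models, rng,
                               factory.ledger, factory.log)
        assert intron.sequence == before

    def test_splice_sites_immutable(self, factory, small_models):
        rng = np.random.default_rng(71)
        for _ in range(25):
            f = type(factory)()
            _, intron = self._intron(f)
            donor_cols = intron.cols[:2]
            acceptor_cols = intron.cols[-2:]
            evolve_intron_sequence(intron, 3.0, SimParams(k_indel=1.0),
                                   small_models, rng, f.ledger, f.log)
            assert intron.donor == "GT" and intron.acceptor == "AG"
            assert intron.cols[:2] == donor_cols
            assert intron.cols[-2:] == acceptor_cols
            assert len(intron) >= 4

    def test_substitution_changes_base(self, factory, small_models, rng):
        _, intron = self._intron(factory)
        evolve_intron_sequence(intron, 5.0, SimParams(k_indel=0.0),
                               small_models, rng, factory.ledger,
                               factory.log)
        subs = [r for r in factory.log if r.type == "nt_sub"]
        assert subs
        for r in subs:
            assert r.payload["old"] != r.payload["new"]


class TestGeneSequences:
    def test_zero_branch_fixed_point(self, factory, small_models, rng):
        gene = factory.gene(["AAATTT", "CCCGGG"])
        before = gene.sequence
        evolve_gene_sequences(gene, 0.0, SimParams(), small_models, rng,
                              factory.ledger, factory.log)
        assert gene.sequence == before

    def test_alternation_untouched(self, factory, small_models, rng):
        gene = factory.gene(["AAATTT", "CCCGGG", "TTTAAA"])
        evolve_gene_sequences(gene, 1.0, SimParams(k_indel=0.5),
                              small_models, rng, factory.ledger, factory.log)
        gene.validate()

    def test_per_segment_streams_independent_of_order(self, factory,
                                                      small_models):
        # same per-segment streams => same result regardless of the order
        # segments are visited, because each segment owns its generator
        def run(reverse):
            f = type(factory)()
            gene = f.gene(["AAATTT", "CCCGGG"])
            segs = list(enumerate(gene.segments))
            if reverse:
                segs = segs[::-1]
            from splicesim.sequence import (evolve_exon_sequence,
                                            evolve_intron_sequence)
            for i, seg in segs:
                seg_rng = np.random.default_rng(
                    np.random.SeedSequence(99, spawn_key=(seg.id,)))
                if seg.kind == "exon":
                    evolve_exon_sequence(seg, 0.8, SimParams(), small_models,
                                         seg_rng, f.ledger, f.log, gene=gene,
                                         seg_index=i)
                else:
                    evolve_intron_sequence(seg, 0.8, SimParams(),
                                           small_models, seg_rng, f.ledger,
                                           f.log, gene=gene, seg_index=i)
            return gene.sequence

        assert run(False) == run(True)
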