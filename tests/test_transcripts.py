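"""Transcript-change (TC) events and exon status."""

import numpy as np
import pytest

from splicesim.events import EventLog
from splicesim.genome import build_cdna
from splicesim.params import SimParams
from splicesim.transcripts import (apply_transcript_loss, create_transcript,
                                   evolve_transcripts, exon_status,
                                   expected_tc_counts)


class TestExpectedCounts:
    def test_printed_formula(self):
        lam = expected_tc_counts(5, 0.1, SimParams(k_tc=5.0))
        assert lam["tl"] == pytest.approx(1.0)  # 5 * 0.4 * 5 * 0.1

    def test_zero_branch(self):
        lam = expected_tc_counts(5, 0.0, SimParams())
        assert all(v == 0.0 for v in lam.values())

    def test_default_type_ratios(self):
        lam = expected_tc_counts(3, 0.2, SimParams())
        assert lam["es"] / lam["ir"] == pytest.approx(4.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            expected_tc_counts(-1, 0.1, SimParams())


class TestTranscriptLoss:
    def test_guard_keeps_last_transcript(self, factory, rng):
        gene = factory.gene(["AAA", "CCC"])
        ts = factory.transcript_set(gene, [0, 1])
        apply_transcript_loss(ts, rng, factory.log)
        assert len(ts) == 1
        apply_transcript_loss(ts, rng, factory.log)
        assert len(ts) == 1
        assert any(r.type == "skipped_event" for r in factory.log)

    def test_uniform_choice(self, factory):
        # chi-square against uniform over two transcripts
        n = 10_000
        hits = 0
        rng = np.random.default_rng(31)
        for _ in range(n):
            f = type(factory)()
            gene = f.gene(["AAA", "CCC"])
            ts = f.transcript_set(gene, [0], [1])
            first = ts.transcripts[0].transcript_id
            apply_transcript_loss(ts, rng, f.log)
            hits += ts.transcripts[0].transcript_id == first
        # survivor == first  <=>  the second was removed, p = 1/2
        assert abs(hits / n - 0.5) < 3 * np.sqrt(0.25 / n)


class TestCreation:
    def test_exon_skipping(self, factory, small_models, rng):
        gene = factory.gene(["AAA", "CCC", "GGG"])
        ts = factory.transcript_set(gene, [0, 1, 2])
        t = create_transcript(ts, gene, "es", small_models, rng, factory.log, ids=factory.ids)
        assert t is not None and len(t.exon_refs) == 2
        assert set(t.exon_refs) < set(e.id for e in gene.exons())
        assert t.lineage_id != ts.transcripts[0].lineage_id

    def test_mutually_exclusive_swap(self, factory, small_models, rng):
        gene = factory.gene(["AAA", "CCC", "GGG"])
        e1, e2, e3 = [e.id for e in gene.exons()]
        ts = factory.transcript_set(gene, [0, 1])
        t = create_transcript(ts, gene, "me", small_models, rng, factory.log, ids=factory.ids)
        assert t is not None
        assert t.exon_refs == [e1, e3]  # only the (E2,E3) pair is eligible

    def test_intron_retention(self, factory, small_models, rng):
        gene = factory.gene(["AAA", "CCC"])
        ts = factory.transcript_set(gene, [0, 1])
        t = create_transcript(ts, gene, "ir", small_models, rng, factory.log, ids=factory.ids)
        intron = gene.introns()[0]
        assert t is not None and t.retained_introns == {intron.id}
        seq, cols = build_cdna(gene, t)
        exons = gene.exons()
        assert seq == (exons[0].sequence + intron.sequence
                       + exons[1].sequence)

    def test_intron_retention_needs_adjacency(self, factory, small_models,
                                              rng):
        gene = factory.gene(["AAA", "CCC", "GGG"])
        ts = factory.transcript_set(gene, [0, 2])  # exons not gene-adjacent
        t = create_transcript(ts, gene, "ir", small_models, rng, factory.log, ids=factory.ids)
        assert t is None
        assert any(r.type == "skipped_event" for r in factory.log)

    @pytest.mark.parametrize("side", ["a5", "a3"])
    def test_boundary_shift_frame_and_bounds(self, factory, small_models,
                                             side):
        rng = np.random.default_rng(41)
        intron_seq = "GT" + "A" * 26 + "AG"
        made = 0
        for _ in range(60):
            f = type(factory)()
            gene = f.gene(["AAATTTCCC", "GGGCCCAAA"], [intron_seq])
            ts = f.transcript_set(gene, [0, 1])
            t = create_transcript(ts, gene, side, small_models, rng, f.log, ids=f.ids)
            if t is None:
                continue
            made += 1
            t.validate(gene)
            for eid in t.exon_refs:
                off5, off3 = t.offset_pair(eid)
                assert off5 % 3 == 0 and off3 % 3 == 0
            seq, cols = build_cdna(gene, t)
            assert len(seq) == len(cols) == len(set(cols))
        assert made > 30

    def test_extension_writes_valid_splice_site(self, factory, small_models):
        rng = np.random.default_rng(43)
        extended = 0
        for _ in range(200):
            f = type(factory)()
            gene = f.gene(["AAATTTCCC", "GGGCCCAAA"],
                          ["GT" + "A" * 26 + "AG"])
            ts = f.transcript_set(gene, [0, 1])
            t = create_transcript(ts, gene, "a3", small_models, rng, f.log, ids=f.ids)
            if t is None:
                continue
            eid = gene.exons()[0].id
            off3 = t.offset_pair(eid)[1]
            if off3 <= 0:
                continue
            extended += 1
            intron = gene.introns()[0]
            # a fresh donor dinucleotide sits at the new boundary
            written = "".join(intron.seq[off3:off3 + 2])
            assert set(written) <= set("ACTG")
        assert extended > 10

    def test_duplicate_forms_rejected(self, factory, small_models, rng):
        gene = factory.gene(["AAA", "CCC"])
        ts = factory.transcript_set(gene, [0, 1])
        # the only es products are (E1) and (E2); a third es must fail
        for _ in range(2):
            create_transcript(ts, gene, "es", small_models, rng, factory.log, ids=factory.ids)
        keys = [t.content_key() for t in ts]
        assert len(keys) == len(set(keys))


class TestEvolveTranscripts:
    def test_zero_branch_keeps_lineages(self, factory, small_models, rng):
        gene = factory.gene(["AAA", "CCC"])
        ts = factory.transcript_set(gene, [0], [1])
        lineages = [t.lineage_id for t in ts]
        evolve_transcripts(ts, gene, 0.0, SimParams(), small_models, rng,
                           factory.log)
        assert [t.lineage_id for t in ts] == lineages

    def test_no_loss_means_non_decreasing(self, factory, small_models):
        params = SimParams(tc_tl=0.0, tc_rs=0.45)
        rng = np.random.default_rng(51)
        gene = factory.gene(["AAA", "CCC", "GGG", "TTT"])
        ts = factory.transcript_set(gene, [0, 1], [2, 3])
        evolve_transcripts(ts, gene, 0.4, params, small_models, rng,
                           factory.log, ids=factory.ids)
        assert len(ts) >= 2

    def test_losses_precede_creations_in_log(self, factory, small_models):
        rng = np.random.default_rng(53)
        gene = factory.gene(["AAA", "CCC", "GGG", "TTT"])
        ts = factory.transcript_set(gene, [0, 1], [2, 3], [0, 3])
        evolve_transcripts(ts, gene, 1.5, SimParams(), small_models, rng,
                           factory.log, ids=factory.ids)
        kinds = [("loss" if r.type == "transcript_loss" else "create")
                 for r in factory.log
                 if r.type.startswith("transcript_")]
        if "loss" in kinds and "create" in kinds:
            assert kinds.index("create") > len(kinds) - 1 - \
                kinds[::-1].index("loss")

    def test_copied_transcripts_keep_lineage(self, factory, small_models):
        rng = np.random.default_rng(55)
        gene = factory.gene(["AAA", "CCC", "GGG"])
        ts = factory.transcript_set(gene, [0, 1, 2])
        original = ts.transcripts[0]
        evolve_transcripts(ts, gene, 0.5, SimParams(tc_tl=0.0, tc_rs=0.45),
                           small_models, rng, factory.log, ids=factory.ids)
        assert original in ts.transcripts  # never lost with tc_tl = 0
        new = [t for t in ts if t is not original]
        assert all(t.lineage_id != original.lineage_id for t in new)


class TestExonStatus:
    def test_three_way_classification(self, factory):
        gene = factory.gene(["AAA", "CCC", "GGG"])
        e1, e2, e3 = [e.id for e in gene.exons()]
        ts = factory.transcript_set(gene, [0, 1], [0])
        status = exon_status(gene, ts)
        assert status == {e1: "constitutive", e2: "alternative", e3: "absent"}

    def test_single_transcript_has_no_alternative(self, factory):
        gene = factory.gene(["AAA", "CCC"])
        ts = factory.transcript_set(gene, [0])
        assert set(exon_status(gene, ts).values()) <= {
            "constitutive", "absent"}

    def test_status_partitions_exons(self, factory):
        gene = factory.gene(["AAA"] * 5)
        ts = factory.transcript_set(gene, [0, 1], [1, 2], [0, 4])
        status = exon_status(gene, ts)
        assert set(status) == {e.id for e in gene.exons()}
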