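import dataclasses

import numpy as np
import pytest

from splicesim.context import IdFactory
from splicesim.events import EventLog
from splicesim.genome import Exon, GeneStructure, Intron, Transcript, TranscriptSet
from splicesim.ledger import HomologyLedger
from splicesim.models import LengthModel, build_default_models
from splicesim.params import SimParams


@pytest.fixture(scope="session")
def models():
    return build_default_models()


@pytest.fixture(scope="session")
def small_models(models):
    """Default chains and matrices, but compact genes for fast simulation."""
    return dataclasses.replace(
        models,
        exon_length=LengthModel(kind="exon_length", target_mean=30,
                                target_std=20),
        intron_length=LengthModel(kind="intron_length", target_mean=60,
                                  target_std=40),
        exons_per_transcript=LengthModel(kind="exons_per_transcript",
                                         target_mean=5, target_std=3),
        transcripts_per_gene=LengthModel(kind="transcripts_per_gene",
                                         target_mean=2.5, target_std=1.5),
    )


@pytest.fixture
def params():
    return SimParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class GeneFactory:
    """Hand-build small genes with explicit sequences for unit tests."""

    def __init__(self):
        self.ledger = HomologyLedger()
        self.ids = IdFactory()
        self.log = EventLog()

    def gene(self, exon_seqs, intron_seqs=None, m_max=10):
        n = len(exon_seqs)
        intron_seqs = intron_seqs or ["GT" + "A" * 16 + "AG"] * (n - 1)
        assert len(intron_seqs) == n - 1
        segments = []
        for i, eseq in enumerate(exon_seqs):
            if i > 0:
                iseq = intron_seqs[i - 1]
                segments.append(Intron(self.ids.segment_id(), iseq,
                                       self.ledger.new_columns(len(iseq))))
            segments.append(Exon(self.ids.segment_id(), eseq,
                                 self.ledger.new_columns(len(eseq))))
        gene = GeneStructure(segments, m_max=m_max)
        self.ledger.register_root(
            [c for s in gene.segments for c in s.cols])
        return gene

    def transcript(self, gene, exon_indices, **kwargs):
        exons = gene.exons()
        return Transcript(
            transcript_id=self.ids.transcript_id(),
            lineage_id=self.ids.lineage_id(),
            exon_refs=[exons[i].id for i in exon_indices],
            **kwargs)

    def transcript_set(self, gene, *index_lists):
        return TranscriptSet(
            [self.transcript(gene, idxs) for idxs in index_lists])


@pytest.fixture
def factory():
    return GeneFactory()
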