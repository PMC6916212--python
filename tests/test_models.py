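"""Packaged generative models: tables, samplers, moment contracts."""

import numpy as np
import pytest

from splicesim.models import (
    BASES, SENSE_CODONS, STOP_CODONS, MIN_INTRON_LENGTH, LENGTH_TARGETS,
    CodonMarkovModel, ConfigurationError, IndelLengthModel, LengthModel,
    SpliceSiteDistribution, build_default_models,
    build_codon_substitution_matrix, generate_codon, sample_length,
    sample_splice_sites)
from splicesim.params import SimParams

PRINTED_P1 = {"A": 0.24, "C": 0.31, "T": 0.19, "G": 0.25}
PRINTED_P0 = {"A": 0.29, "C": 0.20, "T": 0.30, "G": 0.21}


def _binomial_band(p, n, k=3.0):
    return k * np.sqrt(p * (1 - p) / n)


class TestPackagedTables:
    def test_all_rows_sum_to_one(self, models):
        assert abs(models.codon_chain.p1.sum() - 1) < 1e-9
        assert np.allclose(models.codon_chain.p2.sum(axis=1), 1, atol=1e-9)
        assert np.allclose(models.codon_chain.p3.sum(axis=1), 1, atol=1e-9)
        assert abs(models.intron_chain.p0.sum() - 1) < 1e-9
        assert abs(sum(p for *_, p in models.splice_sites.categories) - 1) \
            < 1e-9

    def test_tables_match_printed_values(self, models):
        # two-decimal print precision (the first-position row sums to 0.99
        # as printed, hence the renormalization allowance)
        for i, b in enumerate(BASES):
            assert models.codon_chain.p1[i] == pytest.approx(
                PRINTED_P1[b], abs=0.011)
            assert models.intron_chain.p0[i] == pytest.approx(
                PRINTED_P0[b], abs=1e-9)

    def test_inconsistent_table_rejected(self):
        p1 = np.array([0.5, 0.5, 0.5, 0.5])
        p2 = np.full((4, 4), 0.25)
        p3 = np.full((16, 4), 0.25)
        with pytest.raises(ConfigurationError):
            CodonMarkovModel(p1=p1, p2=p2, p3=p3)


N_CODONS = 200_000


@pytest.fixture(scope="module")
def codons(models):
    rng = np.random.default_rng(7)
    return models.codon_chain.generate_codons(N_CODONS, rng)


class TestCodonChainSampling:
    N = N_CODONS

    def test_first_position_frequency(self, models, codons):
        p = models.codon_chain.p1[0]  # A
        freq = sum(c[0] == "A" for c in codons) / self.N
        assert abs(freq - p) < _binomial_band(p, self.N)
        assert abs(freq - 0.24) < _binomial_band(p, self.N) + 0.005

    def test_second_position_conditional(self, models, codons):
        startA = [c for c in codons if c[0] == "A"]
        p = models.codon_chain.p2[0, 1]  # C | A
        freq = sum(c[1] == "C" for c in startA) / len(startA)
        assert abs(freq - p) < _binomial_band(p, len(startA))
        assert freq == pytest.approx(0.28, abs=0.01)

    def test_third_position_conditional(self, models, codons):
        startTA = [c for c in codons if c[:2] == "TA"]
        p = models.codon_chain.p3[4 * 2 + 0, 1]  # C | TA
        freq = sum(c[2] == "C" for c in startTA) / len(startTA)
        assert abs(freq - p) < _binomial_band(p, len(startTA))
        assert freq == pytest.approx(0.64, abs=0.02)

    def test_stop_codons_not_filtered(self, models, codons):
        # TAA frequency implied by the chains is small but nonzero
        expected = models.codon_chain.codon_frequencies()["TAA"]
        assert expected > 0
        freq = sum(c == "TAA" for c in codons) / self.N
        assert abs(freq - expected) < _binomial_band(expected, self.N)

    def test_single_draw_matches_alphabet(self, models, rng):
        codon = generate_codon(models.codon_chain, rng)
        assert len(codon) == 3 and set(codon) <= set(BASES)


class TestSpliceSites:
    def test_category_frequencies(self, models):
        rng = np.random.default_rng(11)
        n = 10_000
        draws = [sample_splice_sites(models.splice_sites, rng)
                 for _ in range(n)]
        gtag = sum(d == ("GT", "AG") for d in draws) / n
        gcag = sum(d == ("GC", "AG") for d in draws) / n
        assert abs(gtag - 0.98) < _binomial_band(0.98, n)
        assert abs(gcag - 0.01) < _binomial_band(0.01, n)

    def test_other_category_avoids_named_pairs(self, models):
        rng = np.random.default_rng(13)
        draws = [sample_splice_sites(models.splice_sites, rng)
                 for _ in range(5000)]
        others = [d for d in draws if d not in (("GT", "AG"), ("GC", "AG"))]
        assert others  # ~1% of 5000
        for donor, acceptor in others:
            assert len(donor) == len(acceptor) == 2

    def test_point_mass(self, rng):
        dist = SpliceSiteDistribution(categories=(("GT", "AG", 1.0),))
        assert all(dist.sample(rng) == ("GT", "AG") for _ in range(50))


class TestLengthModels:
    @pytest.mark.parametrize("kind", sorted(LENGTH_TARGETS))
    def test_calibrated_law_matches_target_moments(self, models, kind):
        lm = getattr(models, kind)
        mean, std = lm.exact_moments()
        assert mean == pytest.approx(LENGTH_TARGETS[kind][0], rel=0.02)
        assert std == pytest.approx(LENGTH_TARGETS[kind][1], rel=0.02)

    @pytest.mark.parametrize("kind", sorted(LENGTH_TARGETS))
    def test_sampled_mean_within_two_percent(self, models, kind):
        rng = np.random.default_rng(17)
        x = getattr(models, kind).sample_many(1_000_000, rng)
        assert x.mean() == pytest.approx(LENGTH_TARGETS[kind][0], rel=0.02)

    @pytest.mark.parametrize(
        "kind", ["exon_length", "exons_per_transcript",
                 "transcripts_per_gene"])
    def test_sampled_std_light_tails(self, models, kind):
        rng = np.random.default_rng(19)
        x = getattr(models, kind).sample_many(1_000_000, rng)
        assert x.std() == pytest.approx(LENGTH_TARGETS[kind][1], rel=0.02)

    def test_kind_constraints(self, models):
        rng = np.random.default_rng(23)
        ex = models.exon_length.sample_many(100_000, rng)
        assert np.all(ex % 3 == 0) and np.all(ex >= 3)
        intr = models.intron_length.sample_many(100_000, rng)
        assert np.all(intr >= MIN_INTRON_LENGTH)
        for kind in ("exons_per_transcript", "transcripts_per_gene"):
            c = getattr(models, kind).sample_many(100_000, rng)
            assert np.all(c >= 1) and np.issubdtype(c.dtype, np.integer)

    def test_single_draw_api(self, models, rng):
        assert sample_length(models.exon_length, rng) % 3 == 0

    def test_truncated_sample_respects_bounds(self, models, rng):
        for _ in range(200):
            v = models.exons_per_transcript.truncated_sample(rng, 1, 4)
            assert 1 <= v <= 4

    def test_bad_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            LengthModel(kind="nope", target_mean=1, target_std=1)


class TestIndelLengths:
    def test_proper_non_increasing_distribution(self):
        m = IndelLengthModel()
        assert m.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(m.probs) <= 0)
        # normalization equals direct summation of unnormalized weights
        k = np.arange(1, m.max_length + 1, dtype=float)
        w = k ** (-m.alpha)
        assert np.allclose(m.probs, w / w.sum())

    def test_sample_range(self, rng):
        m = IndelLengthModel(max_length=5)
        draws = {m.sample(rng) for _ in range(2000)}
        assert draws <= set(range(1, 6)) and 1 in draws


class TestCodonMatrix:
    def test_rows_stochastic_zero_diagonal(self, models):
        p = models.codon_matrix.probs
        assert np.max(np.abs(p.sum(axis=1) - 1.0)) < 1e-9
        assert np.all(np.diag(p) == 0)
        assert p.shape == (61, 61)

    def test_substitution_always_changes_codon(self, models, rng):
        for codon in ("ATG", "TGG", "AAA"):
            for _ in range(50):
                assert models.codon_matrix.sample_target(codon, rng) != codon

    def test_stop_codon_draws_sense_codon(self, models, rng):
        for stop in STOP_CODONS:
            targets = {models.codon_matrix.sample_target(stop, rng)
                       for _ in range(200)}
            assert targets <= set(SENSE_CODONS)

    def test_frequency_weighting(self, models):
        mat = build_codon_substitution_matrix(models.codon_chain)
        # single-transition targets outweigh single-transversion targets
        i = SENSE_CODONS.index("AAA")
        j_ts = SENSE_CODONS.index("AAG")  # A->G transition at pos 3
        j_tv = SENSE_CODONS.index("AAT")  # A->T transversion at pos 3
        freq = models.codon_chain.codon_frequencies()
        ratio = (mat.probs[i, j_ts] / freq["AAG"]) \
            / (mat.probs[i, j_tv] / freq["AAT"])
        assert ratio == pytest.approx(4.0, rel=1e-6)


class TestSimParams:
    def test_defaults_are_valid_and_printed(self):
        p = SimParams()
        assert (p.k_nbexons, p.k_eic, p.k_tc) == (1.5, 5.0, 5.0)
        assert (p.eic_el, p.eic_eg, p.eic_ed) == (0.4, 0.5, 0.1)
        assert (p.tc_rs, p.tc_a5, p.tc_a3, p.tc_es, p.tc_me, p.tc_ir,
                p.tc_tl) == (0.05, 0.1, 0.1, 0.2, 0.1, 0.05, 0.4)

    @pytest.mark.parametrize("bad", [
        {"eic_el": 0.5},              # frequencies no longer sum to 1
        {"tc_tl": 0.0},
        {"ci": 0.9},
        {"k_eic": -1.0, "eic_el": 0.4},
        {"k_nbexons": 0.5},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SimParams(**bad)
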