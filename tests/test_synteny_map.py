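"""Liftover, reciprocal-best bins, CGI identity, genomic context."""

import numpy as np
import pytest

from litmeth.core import ChainAlignment, GenomicInterval, Transcript
from litmeth import synteny_map as sm
from litmeth.synthetic_cohort import CohortSpec, simulate_annotations

from oracles import brute_liftover


def chain(src, tgt, blocks, cid="c1"):
    return ChainAlignment(src, tgt, tuple(blocks), chain_id=cid, score=1.0)


IDENTITY = chain(GenomicInterval("chr1", 0, 10000),
                 GenomicInterval("chr1", 0, 10000), [(0, 0, 10000)])

# target genome carries a 200 bp insertion after source offset 500
INSERTION = chain(GenomicInterval("chr1", 0, 10000),
                  GenomicInterval("chr1", 0, 10200),
                  [(0, 0, 500), (500, 700, 9500)])


class TestLiftover:
    def test_inside_one_block_translates_exactly(self):
        iv = GenomicInterval("chr1", 100, 300)
        out = sm.liftover(iv, [INSERTION])
        assert out == GenomicInterval("chr1", 100, 300)

    def test_spanning_insertion_returns_covering_span(self):
        iv = GenomicInterval("chr1", 400, 700)
        out = sm.liftover(iv, [INSERTION])
        # all 300 source bases align; covering target span bridges the
        # 200 bp target-side insertion
        assert out == GenomicInterval("chr1", 400, 900)

    def test_interval_in_gap_returns_none(self):
        gap_chain = chain(GenomicInterval("chr1", 0, 10000),
                          GenomicInterval("chr1", 0, 8000),
                          [(0, 0, 4000), (6000, 4000, 4000)])
        assert sm.liftover(GenomicInterval("chr1", 4500, 5500),
                           [gap_chain]) is None

    def test_below_min_match_returns_none(self):
        gap_chain = chain(GenomicInterval("chr1", 0, 10000),
                          GenomicInterval("chr1", 0, 8000),
                          [(0, 0, 4000), (6000, 4000, 4000)])
        # 400 of 1000 bases mapped -> 0.4 < 0.5
        assert sm.liftover(GenomicInterval("chr1", 3600, 4600),
                           [gap_chain]) is None
        out = sm.liftover(GenomicInterval("chr1", 3600, 4600), [gap_chain],
                          min_match=0.3)
        assert out is not None

    def test_agrees_with_per_base_oracle_on_random_intervals(self, rng):
        chains = [INSERTION,
                  chain(GenomicInterval("chr1", 0, 10000),
                        GenomicInterval("chr1", 0, 8000),
                        [(0, 0, 2000), (3000, 2000, 3000), (7000, 5200, 2800)],
                        cid="c2")]
        for c in chains:
            for _ in range(200):
                start = int(rng.integers(0, 9500))
                length = int(rng.integers(1, 500))
                iv = GenomicInterval("chr1", start, start + length)
                ours = sm.liftover(iv, [c])
                ref = brute_liftover(iv, [c])
                if ref is None:
                    assert ours is None
                else:
                    assert ours is not None
                    assert (ours.chrom, ours.start, ours.end) == ref

    def test_agrees_with_oracle_on_cohort_chains(self, small_cohort, rng):
        chains = small_cohort.annotations.chains
        spec = small_cohort.spec
        pair = (spec.species[0], spec.species[1])
        cl = chains[pair]
        size = small_cohort.annotations.per_species[pair[0]].chrom_sizes[spec.chrom]
        for _ in range(100):
            start = int(rng.integers(0, size - 1200))
            iv = GenomicInterval(spec.chrom, start, start + int(rng.integers(50, 1200)))
            ours = sm.liftover(iv, cl)
            ref = brute_liftover(iv, cl)
            if ref is None:
                assert ours is None
            else:
                assert ours is not None and (ours.chrom, ours.start, ours.end) == ref


def tile(size, width=1000, chrom="chr1"):
    return [GenomicInterval(chrom, s, min(s + width, size))
            for s in range(0, size, width)]


class TestReciprocalBest:
    def test_identity_chains_pair_positional_twins(self):
        bins = tile(10000)
        pairs = sm.reciprocal_best_pairs(bins, bins, [IDENTITY], [IDENTITY])
        assert len(pairs) == len(bins)
        assert all(a == b for a, b in pairs)

    def test_pairing_is_a_partial_matching(self, small_cohort):
        ann = small_cohort.annotations
        spec = small_cohort.spec
        a, b = spec.species[0], spec.species[1]
        bins_a = tile(ann.per_species[a].chrom_sizes[spec.chrom])
        bins_b = tile(ann.per_species[b].chrom_sizes[spec.chrom])
        pairs = sm.reciprocal_best_pairs(bins_a, bins_b,
                                         ann.chains[(a, b)],
                                         ann.chains[(b, a)])
        assert len({x for x, _ in pairs}) == len(pairs)
        assert len({y for _, y in pairs}) == len(pairs)

    def test_reciprocity_is_symmetric(self, small_cohort):
        ann = small_cohort.annotations
        spec = small_cohort.spec
        a, b = spec.species[0], spec.species[1]
        bins_a = tile(ann.per_species[a].chrom_sizes[spec.chrom])
        bins_b = tile(ann.per_species[b].chrom_sizes[spec.chrom])
        ab = sm.reciprocal_best_pairs(bins_a, bins_b, ann.chains[(a, b)],
                                      ann.chains[(b, a)])
        ba = sm.reciprocal_best_pairs(bins_b, bins_a, ann.chains[(b, a)],
                                      ann.chains[(a, b)])
        assert {(x, y) for x, y in ab} == {(y, x) for x, y in ba}

    def test_private_insertion_bins_have_no_partner(self):
        spec = CohortSpec(species=("a", "b"), genome_length=400_000,
                          n_genes=12, n_shared_ltrs=0, n_private_ltrs=6,
                          n_orphans=0, rng_seed=3)
        ann = simulate_annotations(spec)
        fr_a = ann.frames["a"]
        bins_a = tile(ann.per_species["a"].chrom_sizes[spec.chrom])
        bins_b = tile(ann.per_species["b"].chrom_sizes[spec.chrom])
        pairs = sm.reciprocal_best_pairs(bins_a, bins_b, ann.chains[("a", "b")],
                                         ann.chains[("b", "a")])
        paired_a = {x for x, _ in pairs}
        private = [l for l in ann.truth.ltrs if l.presence == ("a",)]
        assert private
        for l in private:
            s, e = fr_a.ltr_span(l.id)
            fully_inside = [b for b in bins_a if s <= b.start and b.end <= e]
            for b in fully_inside:
                assert b not in paired_a


class TestCGIIdentity:
    def test_perfectly_conserved_cgi_scores_one(self):
        cgi = GenomicInterval("chr1", 2000, 2100)
        assert sm.cgi_identity(cgi, cgi, [IDENTITY]) == pytest.approx(1.0)

    def test_half_overlap_jaccard_is_one_third(self):
        a = GenomicInterval("chr1", 2000, 2100)
        b = GenomicInterval("chr1", 2050, 2150)
        ident = sm.cgi_identity(a, b, [IDENTITY])
        assert ident == pytest.approx(50 / 150)
        assert ident <= sm.IDENTITY_THRESHOLD  # not syntenic

    def test_disjoint_scores_zero(self):
        a = GenomicInterval("chr1", 2000, 2100)
        b = GenomicInterval("chr1", 5000, 5100)
        assert sm.cgi_identity(a, b, [IDENTITY]) == 0.0

    @pytest.mark.parametrize("mode,expected", [
        ("jaccard", 50 / 150), ("smaller", 0.5), ("reciprocal", 0.5),
    ])
    def test_alternative_identity_modes(self, mode, expected):
        a = GenomicInterval("chr1", 2000, 2100)
        b = GenomicInterval("chr1", 2050, 2150)
        assert sm.cgi_identity(a, b, [IDENTITY], mode=mode) == \
            pytest.approx(expected)

    def test_symmetric_on_identity_chains(self, rng):
        for _ in range(20):
            s1 = int(rng.integers(0, 5000))
            s2 = int(rng.integers(0, 5000))
            a = GenomicInterval("chr1", s1, s1 + int(rng.integers(50, 400)))
            b = GenomicInterval("chr1", s2, s2 + int(rng.integers(50, 400)))
            assert sm.cgi_identity(a, b, [IDENTITY]) == \
                pytest.approx(sm.cgi_identity(b, a, [IDENTITY]))

    def test_identity_decreases_with_annotation_divergence(self):
        """Growing CGI-boundary divergence -> lower mean identity."""
        means = []
        for drift in (0, 60, 180):
            spec = CohortSpec(species=("a", "b"), genome_length=600_000,
                              n_genes=18, n_shared_ltrs=5,
                              n_private_ltrs=8, n_orphans=0,
                              cgi_boundary_drift=drift, rng_seed=5)
            ann = simulate_annotations(spec)
            cgis_a = ann.per_species["a"].cgis
            cgis_b = ann.per_species["b"].cgis
            vals = [sm.cgi_identity(x, y, ann.chains[("a", "b")])
                    for x, y in zip(cgis_a, cgis_b)]
            means.append(float(np.mean(vals)))
        assert means[0] == pytest.approx(1.0)
        assert means[0] >= means[1] >= means[2]
        assert means[2] < 0.9


class TestContext:
    def make_gene(self, start=10000, end=20000, strand="+"):
        loc = GenomicInterval("chr1", start, end, strand)
        return Transcript("g1", loc, (loc,), gene_id="g1")

    def test_cgi_on_tss_is_promoter(self):
        g = self.make_gene()
        cgi = GenomicInterval("chr1", 9800, 10300)
        assert sm.classify_context(cgi, [g]) == "promoter"

    def test_interval_one_kb_past_tts_is_genic(self):
        g = self.make_gene()
        iv = GenomicInterval("chr1", 20900, 21100)
        assert sm.is_genic(iv, [g])
        beyond = GenomicInterval("chr1", 22100, 22500)
        assert not sm.is_genic(beyond, [g])

    def test_deep_gene_body_cgi_is_intragenic(self):
        g = self.make_gene()
        cgi = GenomicInterval("chr1", 14000, 14400)
        assert sm.classify_context(cgi, [g]) == "intragenic"

    def test_dead_zone_between_promoter_and_intragenic_is_proximal(self):
        g = self.make_gene()
        cgi = GenomicInterval("chr1", 10300, 10420)
        assert sm.classify_context(cgi, [g], tss_window=100) == "proximal"

    def test_far_interval_is_intergenic(self):
        g = self.make_gene()
        cgi = GenomicInterval("chr1", 50000, 50400)
        assert sm.classify_context(cgi, [g]) == "intergenic"

    def test_minus_strand_gene_tail_extends_upstream_in_coordinates(self):
        g = self.make_gene(strand="-")
        spans = sm.gene_spans([g])
        assert spans[0].start == 8000 and spans[0].end == 20000
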