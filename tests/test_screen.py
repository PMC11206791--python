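"""Genome search, presence thresholds, strand handling, GH counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmoscreen.align import SENSITIVE_SCORING, reverse_complement
from hmoscreen.screen import (
    GenomeIndex,
    HitRecord,
    call_presence,
    frame_disruption,
    gh_family_counts,
    search_genome,
)

from oracle import random_dna


def _hit(identity, coverage, score=100, ins=0, dele=0, query_id="g"):
    return HitRecord(
        query_id=query_id, contig_id="c", strand="+",
        q_start=0, q_end=100, t_start=0, t_end=100,
        matches=int(identity), align_cols=100,
        identity_pct=identity, coverage_pct=coverage, score=score,
        inserted_bases=ins, deleted_bases=dele,
    )


class TestCallPresence:
    def test_just_above_thresholds_is_present(self):
        call = call_presence([_hit(51.0, 51.0)])
        assert call.present

    def test_boundary_is_absent_under_strict_inequality(self):
        assert not call_presence([_hit(50.0, 99.0)]).present
        assert not call_presence([_hit(99.0, 50.0)]).present
        # inclusive mode admits the boundary
        assert call_presence([_hit(50.0, 50.0)], strict=False).present

    def test_qualifying_hit_preferred_over_higher_scoring_nonqualifier(self):
        high_score_low_cov = _hit(95.0, 40.0, score=500)
        qualifying = _hit(60.0, 80.0, score=300)
        for hits in ([high_score_low_cov, qualifying],
                     [qualifying, high_score_low_cov]):
            call = call_presence(hits)
            assert call.present
            assert call.best_hit == qualifying

    def test_empty_hit_list(self):
        call = call_presence([], query_id="g")
        assert not call.present and call.best_hit is None

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            call_presence([], identity_min=120)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            max_size=5,
        ),
        st.floats(0, 100), st.floats(0, 100),
        st.floats(0, 100), st.floats(0, 100),
    )
    def test_presence_monotone_in_thresholds(self, pairs, i1, c1, i2, c2):
        """Raising either threshold never converts absent -> present."""
        hits = [_hit(i, c) for i, c in pairs]
        lo_i, hi_i = sorted((i1, i2))
        lo_c, hi_c = sorted((c1, c2))
        lo = call_presence(hits, lo_i, lo_c).present
        hi = call_presence(hits, hi_i, hi_c).present
        assert lo or not hi


class TestFrameDisruption:
    @pytest.mark.parametrize(
        "ins,dele,expected",
        [(17, 0, True), (0, 3, False), (4, 1, False), (1, 0, True),
         (0, 0, False)],
    )
    def test_net_indel_mod3(self, ins, dele, expected):
        assert frame_disruption(_hit(99, 99, ins=ins, dele=dele)) is expected


class TestSearchGenome:
    def test_minus_strand_verbatim_plant(self, catalog):
        gene = catalog.genes["lnbX"]
        rng = np.random.default_rng(5)
        bg = random_dna(rng, 8000)
        contig = bg[:3000] + reverse_complement(gene.sequence) + bg[3000:]
        hits = search_genome(gene, [("c1", contig)])
        top = hits[0]
        assert top.strand == "-"
        assert top.identity_pct == 100.0
        assert top.coverage_pct == 100.0
        assert top.t_start == 3000

    def test_absent_gene_low_identity_and_coverage(self, catalog):
        """Random genomes without a planted copy must not look like
        carriers: across seeded replicates the best hit stays far below
        both thresholds."""
        gene = catalog.genes["lnbX"]  # 960 nt
        for seed in range(7, 27):
            genome = [("c1", random_dna(np.random.default_rng(seed), 6000))]
            hits = search_genome(gene, genome, exhaustive=True)
            call = call_presence(hits, query_id=gene.gene_id)
            assert not call.present
            if hits:
                assert hits[0].coverage_pct <= 20.0

    def test_seeded_equals_exhaustive_on_planted_gene(self, catalog):
        from hmoscreen.simulate import mutate_to_identity

        gene = catalog.genes["siaBb2"]
        rng = np.random.default_rng(3)
        planted = mutate_to_identity(gene.sequence, 90.0, rng)
        bg = random_dna(rng, 30_000)
        contig = bg[:11_000] + planted + bg[11_000:]
        genome = [("c1", contig)]
        best_ex = search_genome(gene, genome, exhaustive=True)[0]
        best_seed = search_genome(gene, genome)[0]
        assert best_ex == best_seed

    def test_heuristic_matches_exhaustive_down_to_70pct(self, catalog):
        from hmoscreen.simulate import mutate_to_identity

        gene = catalog.genes["gh20_core"]
        agree = 0
        n = 20
        for seed in range(n):
            rng = np.random.default_rng(1000 + seed)
            ident = float(rng.uniform(70, 99))
            planted = mutate_to_identity(gene.sequence, ident, rng)
            bg = random_dna(rng, 15_000)
            contig = bg[:5000] + planted + bg[5000:]
            genome = [("c1", contig)]
            ex = search_genome(gene, genome, exhaustive=True)[0]
            se = search_genome(gene, genome, seed_k=11)
            agree += bool(se) and se[0].score == ex.score
        assert agree == n

    def test_strand_invariance(self, catalog):
        """Reverse-complementing every contig flips strand labels but
        leaves identity, coverage and presence unchanged."""
        from hmoscreen.simulate import mutate_to_identity

        gene = catalog.genes["nahS"]
        rng = np.random.default_rng(9)
        planted = mutate_to_identity(gene.sequence, 92.0, rng)
        bg = random_dna(rng, 12_000)
        contig = bg[:4000] + planted + bg[4000:]
        fwd = search_genome(gene, [("c1", contig)])[0]
        rev = search_genome(gene, [("c1", reverse_complement(contig))])[0]
        assert fwd.strand != rev.strand
        assert fwd.identity_pct == pytest.approx(rev.identity_pct)
        assert fwd.coverage_pct == pytest.approx(rev.coverage_pct)
        assert fwd.score == rev.score

    def test_bad_contig_named_in_error(self, catalog):
        with pytest.raises(Exception, match="weird"):
            GenomeIndex([("weird", "ACGTNNN" * 100)])

    def test_small_seed_k_rejected(self):
        with pytest.raises(ValueError):
            GenomeIndex([("c", "ACGT" * 100)], k=5)


class TestGhFamilyCounts:
    def test_counts_present_gh_genes_only(self, catalog):
        calls = {
            "lnbX": call_presence([_hit(99, 99, query_id="lnbX")], query_id="lnbX"),
            "lnpA": call_presence([_hit(99, 99, query_id="lnpA")], query_id="lnpA"),
            "bga42A": call_presence([_hit(99, 99, query_id="bga42A")], query_id="bga42A"),
            "gltA": call_presence([_hit(99, 99, query_id="gltA")], query_id="gltA"),
        }
        counts = gh_family_counts(calls, catalog)
        assert counts["GH136"] == 1
        assert counts["GH112"] == 1
        assert counts["GH42"] == 1
        assert counts["GH2"] == 0  # SBP gltA does not count anywhere

    def test_no_present_genes_gives_all_zero_map(self, catalog):
        calls = {"lnbX": call_presence([], query_id="lnbX")}
        counts = gh_family_counts(calls, catalog)
        assert set(counts) == set(catalog.gh_families())
        assert all(v == 0 for v in counts.values())

    def test_two_planted_gh20_homologs_count_two(self, catalog):
        calls = {
            g: call_presence([_hit(98, 98, query_id=g)], query_id=g)
            for g in ("gh20_core", "gh20_aux")
        }
        assert gh_family_counts(calls, catalog)["GH20"] == 2
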