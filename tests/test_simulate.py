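"""Synthetic genomes and cohorts: controllability and determinism."""

import numpy as np
import pytest

from hmoscreen.align import local_align
from hmoscreen.screen import call_presence, search_genome
from hmoscreen.simulate import (
    Plant,
    SimulationError,
    StrainSpec,
    build_genome,
    mutate_to_identity,
    simulate_cohort,
    truth_genotype,
)


class TestMutateToIdentity:
    def test_target_100_is_identity(self, catalog):
        seq = catalog.genes["lnbX"].sequence
        assert mutate_to_identity(seq, 100.0, 1) == seq

    def test_deterministic(self, catalog):
        seq = catalog.genes["lnbX"].sequence
        assert mutate_to_identity(seq, 90.0, 5) == \
            mutate_to_identity(seq, 90.0, 5)

    def test_realized_identity_near_target(self, catalog):
        """Binomial concentration: a 90% target on ~1 kb lands within
        +/- 2 points as measured by the aligner itself."""
        seq = catalog.genes["lnbX"].sequence  # 960 nt
        mutated = mutate_to_identity(seq, 90.0, 5)
        aln = local_align(seq, mutated)
        assert 88.0 <= aln.identity_pct <= 92.0

    def test_out_of_range_rejected(self, catalog):
        with pytest.raises(SimulationError):
            mutate_to_identity(catalog.genes["lnbX"].sequence, 20.0, 1)


def _spec(plants, length=60_000, gc=0.60):
    return StrainSpec("s1", "B. longum", tuple(plants),
                      genome_length=length, gc_content=gc)


class TestBuildGenome:
    def test_verbatim_plant_round_trips_through_the_screen(self, catalog):
        spec = _spec([Plant("lnbX", identity_pct=100.0)])
        contigs, manifest = build_genome(spec, catalog,
                                         np.random.default_rng(0))
        hits = search_genome(catalog.genes["lnbX"], contigs)
        call = call_presence(hits, query_id="lnbX")
        assert call.present
        assert call.best_hit.identity_pct == 100.0
        assert call.best_hit.coverage_pct == 100.0
        assert manifest["plants"][0]["gene_id"] == "lnbX"

    def test_frameshift_plant_is_flagged(self, catalog):
        from hmoscreen.screen import frame_disruption

        spec = _spec([Plant("lnpA", identity_pct=99.0,
                            frameshift_insert_len=17)])
        contigs, _ = build_genome(spec, catalog, np.random.default_rng(1))
        hits = search_genome(catalog.genes["lnpA"], contigs)
        assert frame_disruption(hits[0])

    def test_low_coverage_plant_is_absent(self, catalog):
        spec = _spec([Plant("bga2A", identity_pct=100.0, coverage=0.45)])
        contigs, _ = build_genome(spec, catalog, np.random.default_rng(2))
        hits = search_genome(catalog.genes["bga2A"], contigs)
        call = call_presence(hits, query_id="bga2A")
        assert not call.present
        assert hits[0].coverage_pct == pytest.approx(45.0, abs=1.0)

    def test_background_gc_within_band(self, catalog):
        for gc in (0.56, 0.60, 0.648):
            spec = _spec([], length=100_000, gc=gc)
            contigs, _ = build_genome(spec, catalog,
                                      np.random.default_rng(3))
            seq = contigs[0][1]
            realized = (seq.count("G") + seq.count("C")) / len(seq)
            assert abs(realized - gc) * 100 <= 1.5

    def test_multi_contig_plants_never_split(self, catalog):
        spec = StrainSpec("s1", "B. longum",
                          tuple(Plant(g) for g in ("lnbX", "lnbY", "gltA")),
                          genome_length=60_000, gc_content=0.6, n_contigs=3)
        contigs, manifest = build_genome(spec, catalog,
                                         np.random.default_rng(4))
        assert len(contigs) == 3
        lengths = {cid: len(seq) for cid, seq in contigs}
        for plant in manifest["plants"]:
            assert 0 <= plant["start"] < plant["end"] <= \
                lengths[plant["contig"]]

    def test_infeasible_packing_is_error(self, catalog):
        spec = _spec([Plant("lnbX"), Plant("lnbY")], length=1500)
        with pytest.raises(SimulationError, match="packing"):
            build_genome(spec, catalog, np.random.default_rng(5))


class TestSimulateCohort:
    def test_same_seed_reproduces_identical_bytes(self, catalog, ruleset):
        specs = [_spec([Plant("lnbX"), Plant("lnbY")], length=20_000)]
        a = simulate_cohort(specs, catalog, ruleset, seed=42)
        b = simulate_cohort(specs, catalog, ruleset, seed=42)
        assert a.genomes["s1"] == b.genomes["s1"]
        assert a.plate_frame().equals(b.plate_frame())

    def test_different_seed_changes_genome(self, catalog, ruleset):
        specs = [_spec([Plant("lnbX")], length=20_000)]
        a = simulate_cohort(specs, catalog, ruleset, seed=1)
        b = simulate_cohort(specs, catalog, ruleset, seed=2)
        assert a.genomes["s1"] != b.genomes["s1"]

    def test_noiseless_plate_reflects_truth_categories(self, catalog,
                                                       ruleset):
        specs = [_spec([Plant(g) for g in
                        ("gltA", "gltB", "gltC", "lnpA", "nahK",
                         "galT", "galE", "bga42A")], length=30_000)]
        sim = simulate_cohort(specs, catalog, ruleset, seed=0)
        truth = {p.substrate: p.predicted
                 for p in sim.predictions["s1"]}
        assert truth["LNT"] == "growth"  # functional lnp + GH42 + GH112
        by_substrate = {r.substrate: r for r in sim.growth_records}
        assert by_substrate["LNT"].category == "good"
        assert by_substrate["FL2p"].category == "none"

    def test_truth_genotype_marks_frameshift_nonfunctional(self, catalog):
        spec = _spec([Plant(g, frameshift_insert_len=17 if g == "lnpA" else 0)
                      for g in ("gltA", "gltB", "gltC", "lnpA", "nahK",
                                "galT", "galE")], length=30_000)
        genotype = truth_genotype(spec, catalog)
        lnp = genotype.locus_calls["lnp"]
        assert lnp.state == "complete"
        assert not lnp.functional
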