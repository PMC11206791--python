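"""Locus states, variant typing, configuration groups, co-occurrence."""

import pytest
from hypothesis import given, settings, strategies as st

from hmoscreen.loci import (
    LocusCallError,
    StrainGenotype,
    assign_config_group,
    build_genotype,
    call_locus,
    cooccurrence,
    type_locus_variant,
)
from hmoscreen.screen import HitRecord, PresenceCall


def _call(gene_id, present, ins=0):
    hit = None
    if present:
        hit = HitRecord(
            query_id=gene_id, contig_id="c", strand="+",
            q_start=0, q_end=100, t_start=0, t_end=100,
            matches=99, align_cols=100, identity_pct=99.0,
            coverage_pct=100.0, score=200,
            inserted_bases=ins, deleted_bases=0,
        )
    return PresenceCall(gene_id, present, hit, 50.0, 50.0, True)


def _presence(catalog, present_genes, disrupted=()):
    return {
        gid: _call(gid, gid in present_genes,
                   ins=17 if gid in disrupted else 0)
        for gid in catalog.genes
    }


class TestCallLocus:
    def test_all_seven_lnp_members_present_is_complete_functional(self, catalog):
        lnp = catalog.loci["lnp"]
        call = call_locus(_presence(catalog, set(lnp.member_gene_ids)), lnp)
        assert call.state == "complete"
        assert call.functional
        assert call.missing_members == ()

    def test_fhmo_without_transporter_is_partial_nonfunctional(self, catalog):
        """Fucosidases plus fucose catabolism present but the FL ABC
        transporter missing: partial and non-functional."""
        fhmo = catalog.loci["FHMO_cluster"]
        present = {"afcA_f", "afcB_f", "fucU", "fhmo_fucD", "fhmo_fucK",
                   "fhmoR"}
        call = call_locus(_presence(catalog, present), fhmo)
        assert call.state == "partial"
        assert not call.functional

    def test_no_members_is_absent(self, catalog):
        call = call_locus(_presence(catalog, set()), catalog.loci["lnp"])
        assert call.state == "absent"
        assert not call.functional

    def test_missing_call_names_gene(self, catalog):
        with pytest.raises(LocusCallError, match="gltA"):
            call_locus({}, catalog.loci["lnp"])

    def test_frame_disrupted_required_member_breaks_function_not_state(
            self, catalog):
        lnp = catalog.loci["lnp"]
        presence = _presence(catalog, set(lnp.member_gene_ids),
                             disrupted={"lnpA"})
        call = call_locus(presence, lnp)
        assert call.state == "complete"
        assert not call.functional

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        present=st.sets(st.sampled_from(
            ["gltA", "gltB", "gltC", "lnpA", "nahK", "galT", "galE"])),
        removed=st.sampled_from(
            ["gltA", "gltB", "gltC", "lnpA", "nahK", "galT", "galE"]),
    )
    def test_removing_a_member_never_improves_the_call(
            self, present, removed, catalog):
        lnp = catalog.loci["lnp"]
        rank = {"absent": 0, "partial": 1, "complete": 2}
        full = call_locus(_presence(catalog, present), lnp)
        reduced = call_locus(_presence(catalog, present - {removed}), lnp)
        assert rank[reduced.state] <= rank[full.state]
        assert full.functional or not reduced.functional


class TestVariantTyping:
    def _hits(self, identities):
        return {
            gid: [HitRecord(
                query_id=gid, contig_id="c", strand="+", q_start=0,
                q_end=100, t_start=0, t_end=100, matches=int(ident),
                align_cols=100, identity_pct=ident, coverage_pct=100.0,
                score=100, inserted_bases=0, deleted_bases=0)]
            for gid, ident in identities.items()
        }

    def test_higher_mean_identity_wins(self, catalog):
        hits = self._hits({
            "gltA_adult": 99.0, "gltB_adult": 99.2, "gltC_adult": 98.8,
            "gltA_infant": 92.0, "gltB_infant": 92.4, "gltC_infant": 91.6,
        })
        assert type_locus_variant(hits, catalog.loci["lnp"]) == "adult"

    def test_tie_is_ambiguous(self, catalog):
        hits = self._hits({"gltA_adult": 95.0, "gltA_infant": 95.0})
        assert type_locus_variant(hits, catalog.loci["lnp"]) == "ambiguous"

    def test_hits_only_to_one_variant(self, catalog):
        hits = self._hits({"gltA_infant": 97.0, "gltB_infant": 96.0})
        assert type_locus_variant(hits, catalog.loci["lnp"]) == "infant"

    def test_no_hits_returns_none(self, catalog):
        assert type_locus_variant({}, catalog.loci["lnp"]) is None

    def test_symmetric_under_relabeling(self, catalog):
        """Swapping which identities belong to which label swaps the
        answer but never changes whether a decision is made."""
        lnp = catalog.loci["lnp"]
        a = self._hits({"gltA_adult": 99.0, "gltA_infant": 92.0})
        b = self._hits({"gltA_adult": 92.0, "gltA_infant": 99.0})
        assert type_locus_variant(a, lnp) == "adult"
        assert type_locus_variant(b, lnp) == "infant"


class TestConfigGroups:
    def _genotype(self, catalog, present):
        presence = _presence(catalog, present)
        hits = {g: [] for g in catalog.genes}
        return build_genotype("s", "B. infantis", hits, presence, catalog)

    GLTABC = {"gltA", "gltB", "gltC"}
    FL3 = {"fl1_IV_sbp", "fl3_perm1", "fl3_perm2", "gh151_fl3"}
    H2 = {"fucT1", "fucT2", "fucT3"}

    def test_full_machinery_is_group_i(self, catalog):
        g = self._genotype(
            catalog, self.GLTABC | {"nahS"} | self.FL3 | self.H2)
        assert g.config_group == "I"

    def test_group_ii(self, catalog):
        g = self._genotype(catalog, self.FL3 | self.H2)
        assert g.config_group == "II"

    def test_group_iii(self, catalog):
        g = self._genotype(catalog, self.H2)
        assert g.config_group == "III"

    def test_group_iv(self, catalog):
        g = self._genotype(catalog, {"nahS", "fucT1"})
        assert g.config_group == "IV"

    def test_unmatched_pattern_is_unclassified(self, catalog):
        # nahS present, FL3 present, gltABC absent matches no group
        g = self._genotype(catalog, {"nahS"} | self.FL3 | self.H2)
        assert g.config_group == "unclassified"

    def test_other_species_not_applicable(self, catalog):
        presence = _presence(catalog, set())
        g = build_genotype("s", "B. breve", {g: [] for g in catalog.genes},
                           presence, catalog)
        assert g.config_group == "not_applicable"


class TestCooccurrence:
    def test_all_carriers_also_carry_partner(self):
        table = {f"s{i}": {"lnbX": i < 43, "lnbY": i < 43}
                 for i in range(67)}
        exact, rounded = cooccurrence(table, "lnbX", "lnbY")
        assert exact == 100.0 and rounded == 100

    def test_quarter(self):
        table = {"a": {"x": True, "y": True}, "b": {"x": True},
                 "c": {"x": True}, "d": {"x": True}}
        exact, rounded = cooccurrence(table, "x", "y")
        assert exact == 25.0 and rounded == 25

    def test_zero_carriers_is_error(self):
        with pytest.raises(LocusCallError, match="undefined"):
            cooccurrence({"a": {"x": False}}, "x", "y")
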