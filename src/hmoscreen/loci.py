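"""Locus-level genotype calling on top of per-gene presence calls.

Converts presence calls into locus states (complete / partial / absent),
functionality flags (all transporter-critical members present and none
frame-disrupted), locus variant labels (e.g. the adult- vs infant-type
gltABC transporter of the lnp cluster) and, for B. infantis, the four
genetic configuration groups defined by gltABC, nahS, fucosyllactose
cluster 3 and H2 completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .catalog import Catalog, Locus
from .screen import HitRecord, PresenceCall, frame_disruption

LOCUS_STATES = ("complete", "partial", "absent")
CONFIG_GROUPS = ("I", "II", "III", "IV", "unclassified", "not_applicable")

#: species whose strains fall into the four configuration groups
_CONFIG_SPECIES = "B. infantis"


class LocusCallError(ValueError):
    pass


@dataclass(frozen=True)
class LocusCall:
    locus_id: str
    state: str
    missing_members: tuple[str, ...]
    functional: bool
    variant: str | None = None


@dataclass(frozen=True)
class StrainGenotype:
    strain_id: str
    species: str
    presence: Mapping[str, PresenceCall]
    locus_calls: Mapping[str, LocusCall]
    config_group: str = "not_applicable"
    gh_counts: Mapping[str, int] = field(default_factory=dict)

    def gene_present(self, gene_id: str) -> bool:
        call = self.presence.get(gene_id)
        return call is not None and call.present


def _disrupted(call: PresenceCall) -> bool:
    return (
        call.present
        and call.best_hit is not None
        and frame_disruption(call.best_hit)
    )


def call_locus(
    presence: Mapping[str, PresenceCall], locus: Locus
) -> LocusCall:
    """Locus state from member presence.

    complete: every required_for_complete member present;
    absent: no member present; partial otherwise. ``functional`` requires
    every required_for_functional member present AND not frame-disrupted
    (a present gene with a frameshift still counts for the state, mirroring
    a pseudogenized but detectable coding sequence).
    """
    for member in locus.member_gene_ids:
        if member not in presence:
            raise LocusCallError(
                f"locus {locus.locus_id}: no presence call for gene "
                f"{member!r}"
            )
    present = {m for m in locus.member_gene_ids if presence[m].present}
    missing_required = tuple(
        m for m in locus.required_for_complete if m not in present
    )
    if not missing_required:
        state = "complete"
    elif not present:
        state = "absent"
    else:
        state = "partial"
    functional = all(
        presence[m].present and not _disrupted(presence[m])
        for m in locus.required_for_functional
    )
    return LocusCall(
        locus_id=locus.locus_id,
        state=state,
        missing_members=missing_required,
        functional=functional,
    )


def type_locus_variant(
    hits_by_gene: Mapping[str, Sequence[HitRecord]],
    locus: Locus,
    margin_pct: float = 1.0,
) -> str | None:
    """Label the locus variant with the higher mean best-hit identity
    across its reference genes; "ambiguous" when the top two means are
    within ``margin_pct`` points; None when no variant has any hit."""
    if len(locus.variant_refs) < 2:
        raise LocusCallError(
            f"locus {locus.locus_id}: variant typing needs >= 2 variant_refs"
        )
    means: dict[str, float] = {}
    for label, refs in locus.variant_refs.items():
        identities = [
            max(h.identity_pct for h in hits_by_gene[r])
            for r in refs
            if hits_by_gene.get(r)
        ]
        if identities:
            means[label] = sum(identities) / len(identities)
    if not means:
        return None
    if len(means) == 1:
        return next(iter(means))
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    if ranked[0][1] - ranked[1][1] < margin_pct:
        return "ambiguous"
    return ranked[0][0]


def assign_config_group(genotype: StrainGenotype) -> str:
    """The four B. infantis genetic configurations.

    I: gltABC functional; II: gltABC lost, nahS lost, fucosyllactose
    cluster 3 retained and H2 complete; III: gltABC, nahS and cluster 3 all
    lost; IV: gltABC and cluster 3 lost, nahS retained, H2 partial.
    Anything else is unclassified rather than force-assigned.
    """
    if genotype.species != _CONFIG_SPECIES:
        return "not_applicable"
    for locus_id in ("FL_cluster_3", "H2"):
        if locus_id not in genotype.locus_calls:
            raise LocusCallError(
                f"config grouping needs a locus call for {locus_id!r}"
            )
    presence = genotype.presence
    try:
        gltabc = all(
            presence[g].present and not _disrupted(presence[g])
            for g in ("gltA", "gltB", "gltC")
        )
        nahs = presence["nahS"].present
    except KeyError as exc:
        raise LocusCallError(
            f"config grouping needs a presence call for {exc.args[0]!r}"
        ) from None
    fl3 = genotype.locus_calls["FL_cluster_3"].state
    h2 = genotype.locus_calls["H2"].state
    if gltabc:
        return "I"
    if not nahs and fl3 != "absent" and h2 == "complete":
        return "II"
    if not nahs and fl3 == "absent":
        return "III"
    if nahs and fl3 == "absent" and h2 == "partial":
        return "IV"
    return "unclassified"


def build_genotype(
    strain_id: str,
    species: str,
    hits_by_gene: Mapping[str, Sequence[HitRecord]],
    presence: Mapping[str, PresenceCall],
    catalog: Catalog,
    margin_pct: float = 1.0,
    gh_counts: Mapping[str, int] | None = None,
) -> StrainGenotype:
    """Assemble the full per-strain genotype: locus calls (with variant
    labels where defined) and, for B. infantis, the configuration group."""
    locus_calls: dict[str, LocusCall] = {}
    for locus_id, locus in catalog.loci.items():
        call = call_locus(presence, locus)
        if len(locus.variant_refs) >= 2 and call.state != "absent":
            variant = type_locus_variant(hits_by_gene, locus, margin_pct)
            call = LocusCall(
                locus_id=call.locus_id, state=call.state,
                missing_members=call.missing_members,
                functional=call.functional, variant=variant,
            )
        locus_calls[locus_id] = call
    genotype = StrainGenotype(
        strain_id=strain_id,
        species=species,
        presence=dict(presence),
        locus_calls=locus_calls,
        gh_counts=dict(gh_counts or {}),
    )
    if species == _CONFIG_SPECIES:
        group = assign_config_group(genotype)
        genotype = StrainGenotype(
            strain_id=strain_id, species=species,
            presence=genotype.presence, locus_calls=locus_calls,
            config_group=group, gh_counts=genotype.gh_counts,
        )
    return genotype


def cooccurrence(
    presence_by_strain: Mapping[str, Mapping[str, bool]],
    gene_a: str,
    gene_b: str,
) -> tuple[float, int]:
    """Percent of gene_a-positive strains also carrying gene_b.

    Returns (exact percent to float precision, round-half-up integer
    percent). Raises when no strain carries gene_a.
    """
    carriers = [
        s for s, genes in presence_by_strain.items() if genes.get(gene_a)
    ]
    if not carriers:
        raise LocusCallError(
            f"undefined co-occurrence: no strain carries {gene_a!r}"
        )
    both = sum(
        1 for s in carriers if presence_by_strain[s].get(gene_b, False)
    )
    pct = 100.0 * both / len(carriers)
    return pct, int(pct + 0.5)
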