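"""Cohort-scale gene-trait statistics on a simulated B. longum panel.

Simulates a scaled-down B. longum cohort, screens the lnbX/lnbY genes and
the two gltABC transporter versions, and prints prevalence, co-occurrence,
variant fractions and the lnbX growth advantage on LNT.
"""

from hmoscreen import (
    GenomeIndex,
    call_presence,
    compare_groups,
    default_catalog,
    prevalence,
    search_genome,
    simulate_cohort,
)
from hmoscreen.loci import cooccurrence, type_locus_variant
from hmoscreen.simulate import longum_cohort

catalog = default_catalog()
# 20-strain panel with the reference cohort's carrier fractions scaled down
specs = longum_cohort(n=20, lnbx_carriers=13, adult_variant=14,
                      bga2a_carriers=15, genome_length=100_000)
sim = simulate_cohort(specs, catalog, seed=9)

genes = ("lnbX", "lnbY", "gltA_adult", "gltB_adult", "gltC_adult",
         "gltA_infant", "gltB_infant", "gltC_infant")
table, variants = {}, []
for spec in specs:
    index = GenomeIndex(sim.genomes[spec.strain_id])
    hits = {g: search_genome(catalog.genes[g], index) for g in genes}
    table[spec.strain_id] = {
        g: call_presence(hits[g], query_id=g).present for g in genes}
    variants.append(type_locus_variant(hits, catalog.loci["lnp"]))

prev = prevalence(table, "lnbX")
print(f"lnbX prevalence: {prev.carrier_count}/{prev.cohort_size} "
      f"({prev.prevalence_pct}%)")
exact, _ = cooccurrence(table, "lnbX", "lnbY")
print(f"lnbY co-occurrence among lnbX+: {exact:.0f}%")
adult = sum(v == "adult" for v in variants)
print(f"adult-type gltABC: {adult}/{len(variants)} "
      f"({100 * adult / len(variants):.0f}%)")

carriers = {s for s in table if table[s]["lnbX"]}
cmp = compare_groups(list(sim.growth_records), lambda s: s in carriers,
                     "LNT", label_a="lnbX+", label_b="lnbX-")
print(f"LNT delta OD lnbX+ vs lnbX-: {cmp.mean_a:.2f} vs {cmp.mean_b:.2f} "
      f"(Welch p={cmp.p_two_sided:.2g})")

# The extracellular lacto-N-biosidase route (lnbX + chaperone lnbY) always
# co-occurs and carries a reproducible LNT growth advantage; transporter
# variant typing splits the cohort into adult- and infant-like lnp types.
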