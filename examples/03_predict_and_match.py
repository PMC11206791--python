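"""Predict growth from genotype and match against a measured plate.

Simulates the B. catenulatum contrast (half the strains carry the LNB/LNT
utilization cluster), predicts growth on the six HMOs from the screened
genotypes, matches predictions against the simulated OD600 plate, and
runs the Welch comparison between cluster+ and cluster- strains on LNT.
"""

from hmoscreen import (
    compare_groups,
    concordance,
    default_catalog,
    default_rules,
    predict_growth,
    simulate_cohort,
)
from hmoscreen.pipeline import RunConfig, screen_strain
from hmoscreen.simulate import catenulatum_cohort

catalog = default_catalog()
ruleset = default_rules(catalog)
specs = catenulatum_cohort(n=8, cluster_carriers=4, genome_length=60_000)
sim = simulate_cohort(specs, catalog, ruleset, seed=3)

config = RunConfig(genomes_dir=".", out_dir=".")
predictions = []
carriers = set()
for spec in specs:
    res = screen_strain(spec.strain_id, spec.species,
                        sim.genomes[spec.strain_id], catalog, config)
    if res.genotype.locus_calls["LNB_LNT_cluster"].functional:
        carriers.add(spec.strain_id)
    predictions.extend(predict_growth(res.genotype, ruleset, catalog))

for p in predictions:
    if p.substrate == "LNT":
        print(f"{p.strain_id:16s} LNT predicted={p.predicted:9s} "
              f"via {p.rule_name}")

conc = concordance(predictions, list(sim.growth_records))
print(f"\nprediction/observation agreement: {conc.agreement_pct:.0f}%")

cmp = compare_groups(list(sim.growth_records), lambda s: s in carriers,
                     "LNT", level="replicate",
                     label_a="cluster+", label_b="cluster-")
print(f"LNT growth {cmp.label_a} vs {cmp.label_b}: "
      f"{cmp.mean_a:.2f} vs {cmp.mean_b:.2f} OD, "
      f"Welch t={cmp.welch_t:.2f}, p={cmp.p_two_sided:.2g}")

# Cluster carriers are predicted to grow on LNT and measured around the
# moderate 0.70 OD anchor; non-carriers sit at the ~0.32 residual
# baseline, below the 0.4 growth threshold, giving a strongly significant
# Welch contrast at replicate level. With the assay-realistic 0.14 OD
# replicate noise a borderline well can occasionally cross the 0.4
# category line, so agreement on noisy plates sits just below the 100%
# achieved on noise-free cohorts.
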