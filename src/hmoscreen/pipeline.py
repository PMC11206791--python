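"""End-to-end orchestration: screen genomes, call loci, predict growth,
match against plates, and export the per-cohort matrices and summaries.

Every stage consumes and produces documented plain-text formats (FASTA in,
TSV/JSON out), so stages are independently re-runnable and the whole
bundle is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .catalog import Catalog, default_catalog, load_catalog
from .cohort_stats import (
    CohortStatsError,
    concordance,
    conservation,
    prevalence,
)
from .growth import GrowthRecord, read_plate
from .loci import StrainGenotype, build_genotype
from .rules import RuleSet, SUBSTRATES, default_rules, load_rules, predict_growth
from .screen import (
    DEFAULT_SCORING,
    GenomeIndex,
    HitRecord,
    PresenceCall,
    ScoringScheme,
    call_presence,
    frame_disruption,
    gh_family_counts,
    search_genome,
)

HIT_COLUMNS = (
    "query_id", "contig", "strand", "identity_pct", "coverage_pct",
    "q_start", "q_end", "t_start", "t_end", "score", "frame_disrupted",
)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    genomes_dir: str
    out_dir: str
    growth_table: str | None = None
    catalog_fasta: str | None = None
    catalog_metadata: str | None = None
    catalog_loci: str | None = None
    rules_path: str | None = None
    identity_min: float = 50.0
    coverage_min: float = 50.0
    strict: bool = True
    exhaustive: bool = False
    seed_k: int = 11
    level: str = "strain"
    seed: int = 0
    scoring: ScoringScheme = DEFAULT_SCORING
    species_map: Mapping[str, str] = field(default_factory=dict)


@dataclass
class StrainResult:
    strain_id: str
    species: str
    hits: dict[str, list[HitRecord]]
    presence: dict[str, PresenceCall]
    genotype: StrainGenotype


@dataclass
class PipelineResult:
    catalog: Catalog
    ruleset: RuleSet
    strains: list[StrainResult]
    predictions: dict[str, list]
    growth_records: list[GrowthRecord]


def _load_inputs(config: RunConfig) -> tuple[Catalog, RuleSet]:
    if config.catalog_fasta:
        catalog = load_catalog(
            config.catalog_fasta, config.catalog_metadata, config.catalog_loci
        )
    else:
        catalog = default_catalog()
    ruleset = (
        load_rules(config.rules_path, catalog)
        if config.rules_path else default_rules(catalog)
    )
    return catalog, ruleset


def _infer_species(strain_id: str, config: RunConfig) -> str:
    if strain_id in config.species_map:
        return config.species_map[strain_id]
    prefixes = {
        "breve": "B. breve", "infantis": "B. infantis",
        "longum": "B. longum", "bifidum": "B. bifidum",
        "pseudocat": "B. pseudocatenulatum",
        "catenulatum": "B. catenulatum",
        "adolescentis": "B. adolescentis", "scardovii": "B. scardovii",
        "animalis": "B. animalis", "angulatum": "B. angulatum",
    }
    for prefix, species in prefixes.items():
        if strain_id.startswith(prefix):
            return species
    return "unknown"


def read_genomes(genomes_dir: str | Path) -> dict[str, list[tuple[str, str]]]:
    """One FASTA per strain (stem = strain id), multiple contigs allowed."""
    genomes: dict[str, list[tuple[str, str]]] = {}
    paths = sorted(Path(genomes_dir).glob("*.fasta")) + sorted(
        Path(genomes_dir).glob("*.fa")
    )
    if not paths:
        raise PipelineError(f"no FASTA files in {genomes_dir}")
    for path in paths:
        genomes[path.stem] = [
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    return genomes


def screen_strain(
    strain_id: str,
    species: str,
    contigs: Sequence[tuple[str, str]],
    catalog: Catalog,
    config: RunConfig,
) -> StrainResult:
    index = None if config.exhaustive else GenomeIndex(
        contigs, k=config.seed_k)
    hits: dict[str, list[HitRecord]] = {}
    presence: dict[str, PresenceCall] = {}
    for gid, gene in catalog.genes.items():
        gene_hits = search_genome(
            gene, index if index is not None else contigs,
            scoring=config.scoring, seed_k=config.seed_k,
            exhaustive=config.exhaustive,
        )
        hits[gid] = gene_hits
        presence[gid] = call_presence(
            gene_hits, config.identity_min, config.coverage_min,
            config.strict, query_id=gid,
        )
    counts = gh_family_counts(presence, catalog)
    genotype = build_genotype(
        strain_id, species, hits, presence, catalog, gh_counts=counts)
    return StrainResult(strain_id, species, hits, presence, genotype)


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _hits_frame(strains: Sequence[StrainResult]) -> pd.DataFrame:
    rows = []
    for s in strains:
        for gid, hits in s.hits.items():
            for h in hits:
                rows.append({
                    "strain": s.strain_id, "query_id": h.query_id,
                    "contig": h.contig_id, "strand": h.strand,
                    "identity_pct": round(h.identity_pct, 2),
                    "coverage_pct": round(h.coverage_pct, 2),
                    "q_start": h.q_start, "q_end": h.q_end,
                    "t_start": h.t_start, "t_end": h.t_end,
                    "score": h.score,
                    "frame_disrupted": int(frame_disruption(h)),
                })
    return pd.DataFrame(rows, columns=("strain",) + HIT_COLUMNS)


def export_matrices(
    strains: Sequence[StrainResult],
    growth_records: Sequence[GrowthRecord],
    catalog: Catalog,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(strain x gene identity matrix, strain x substrate delta-OD matrix).

    Rows are strains sorted by species then id; gene columns follow catalog
    order; absent genes are empty cells, present ones carry the best-hit
    identity to one decimal.
    """
    ordered = sorted(strains, key=lambda s: (s.species, s.strain_id))
    identity_rows = {}
    for s in ordered:
        row = {}
        for gid in catalog.gene_order:
            call = s.presence.get(gid)
            row[gid] = (
                f"{call.best_hit.identity_pct:.1f}"
                if call is not None and call.present and call.best_hit
                else ""
            )
        identity_rows[s.strain_id] = row
    identity = pd.DataFrame.from_dict(identity_rows, orient="index")
    identity = identity.reindex(columns=list(catalog.gene_order))
    identity.index.name = "strain"

    growth_map: dict[str, dict[str, float]] = {}
    for rec in growth_records:
        growth_map.setdefault(rec.strain_id, {})[rec.substrate] = round(
            rec.delta_od, 3)
    growth = pd.DataFrame.from_dict(growth_map, orient="index")
    growth = growth.reindex(
        index=[s.strain_id for s in ordered if s.strain_id in growth_map],
        columns=[s for s in SUBSTRATES],
    )
    growth.index.name = "strain"
    return identity, growth


def summarize_cohort(
    strains: Sequence[StrainResult], catalog: Catalog
) -> pd.DataFrame:
    """Per (species, gene): prevalence and conservation of best hits."""
    presence_by_strain = {
        s.strain_id: {g: c.present for g, c in s.presence.items()}
        for s in strains
    }
    species_by_strain = {s.strain_id: s.species for s in strains}
    rows = []
    for species in sorted({s.species for s in strains}):
        members = [s for s in strains if s.species == species]
        for gid in catalog.gene_order:
            prev = prevalence(
                presence_by_strain, gid, species_by_strain, species)
            identities = {
                s.strain_id: (
                    s.presence[gid].best_hit.identity_pct
                    if s.presence[gid].present and s.presence[gid].best_hit
                    else None
                )
                for s in members
            }
            row = {
                "species": species, "gene_id": gid,
                "carrier_count": prev.carrier_count,
                "cohort_size": prev.cohort_size,
                "prevalence_pct": prev.prevalence_pct,
                "prevalence_exact": round(prev.prevalence_exact, 2),
            }
            try:
                cons = conservation(identities, gid)
                row["identity_mean"] = round(cons.identity_mean, 2)
                row["identity_sd"] = round(cons.identity_sd, 2)
            except CohortStatsError:
                row["identity_mean"] = ""
                row["identity_sd"] = ""
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages and write the output bundle under ``config.out_dir``.

    Genotype-level outputs are written before the growth stage runs, so a
    missing growth table still leaves a usable genotype bundle behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"hmoscreen {__version__}",
        f"started {datetime.datetime.now().isoformat(timespec='seconds')}",
        f"config {json.dumps(dataclasses.asdict(config), default=str)}",
    ]

    try:
        catalog, ruleset = _load_inputs(config)
        genomes = read_genomes(config.genomes_dir)
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc

    strains: list[StrainResult] = []
    for strain_id in sorted(genomes):
        species = _infer_species(strain_id, config)
        try:
            strains.append(screen_strain(
                strain_id, species, genomes[strain_id], catalog, config))
        except Exception as exc:
            raise PipelineError(
                f"screen stage: strain {strain_id!r}: {exc}") from exc
        log_lines.append(f"screened {strain_id} ({species})")

    hits_df = _hits_frame(strains)
    _atomic_write(out / "hits.tsv", hits_df.to_csv(sep="\t", index=False))

    presence_rows = [
        {
            "strain": s.strain_id, "gene_id": gid,
            "present": int(call.present),
            "identity_pct": (
                round(call.best_hit.identity_pct, 2) if call.best_hit else ""
            ),
            "coverage_pct": (
                round(call.best_hit.coverage_pct, 2) if call.best_hit else ""
            ),
        }
        for s in strains for gid, call in s.presence.items()
    ]
    _atomic_write(
        out / "presence.tsv",
        pd.DataFrame(presence_rows).to_csv(sep="\t", index=False),
    )

    locus_rows = [
        {
            "strain": s.strain_id, "locus": lid, "state": call.state,
            "functional": int(call.functional),
            "variant": call.variant or "",
            "missing_members": ";".join(call.missing_members),
        }
        for s in strains for lid, call in s.genotype.locus_calls.items()
    ]
    _atomic_write(
        out / "locus_calls.tsv",
        pd.DataFrame(locus_rows).to_csv(sep="\t", index=False),
    )

    genotype_bundle = {
        s.strain_id: {
            "species": s.species,
            "config_group": s.genotype.config_group,
            "gh_counts": dict(s.genotype.gh_counts),
            "present_genes": sorted(
                g for g, c in s.presence.items() if c.present),
        }
        for s in strains
    }
    _atomic_write(out / "genotypes.json",
                  json.dumps(genotype_bundle, indent=1, sort_keys=True))

    summary = summarize_cohort(strains, catalog)
    _atomic_write(out / "prevalence_conservation.tsv",
                  summary.to_csv(sep="\t", index=False))

    try:
        predictions = {
            s.strain_id: predict_growth(s.genotype, ruleset, catalog)
            for s in strains
        }
    except Exception as exc:
        raise PipelineError(f"predict stage: {exc}") from exc
    pred_rows = [
        {
            "strain": sid, "substrate": p.substrate,
            "predicted": p.predicted, "rule": p.rule_name,
            "trace": "&".join(p.rule_trace),
        }
        for sid, preds in predictions.items() for p in preds
    ]
    _atomic_write(out / "predictions.tsv",
                  pd.DataFrame(pred_rows).to_csv(sep="\t", index=False))

    growth_records: list[GrowthRecord] = []
    if config.growth_table is not None:
        try:
            growth_records = read_plate(config.growth_table)
        except Exception as exc:
            _atomic_write(out / "run.log", "\n".join(
                log_lines + [f"growth stage failed: {exc}"]) + "\n")
            raise PipelineError(f"growth stage: {exc}") from exc
        growth_rows = [
            {
                "strain": r.strain_id, "substrate": r.substrate,
                "delta_od": f"{r.delta_od:.3f}", "category": r.category,
            }
            for r in growth_records
        ]
        _atomic_write(out / "growth.tsv",
                      pd.DataFrame(growth_rows).to_csv(sep="\t", index=False))
        all_preds = [p for preds in predictions.values() for p in preds]
        try:
            conc = concordance(all_preds, growth_records)
            _atomic_write(out / "concordance.json", json.dumps(
                {
                    "per_substrate": {
                        k: dict(v) for k, v in conc.per_substrate.items()
                    },
                    "agreement_pct": round(conc.agreement_pct, 2),
                    "discordant": [list(d) for d in conc.discordant],
                },
                indent=1,
            ))
        except CohortStatsError as exc:
            log_lines.append(f"concordance skipped: {exc}")

    identity_m, growth_m = export_matrices(strains, growth_records, catalog)
    _atomic_write(out / "identity_matrix.tsv", identity_m.to_csv(sep="\t"))
    if not growth_m.empty:
        _atomic_write(out / "growth_matrix.tsv", growth_m.to_csv(sep="\t"))

    log_lines.append("done")
    _atomic_write(out / "run.log", "\n".join(log_lines) + "\n")
    return PipelineResult(
        catalog=catalog, ruleset=ruleset, strains=strains,
        predictions=predictions, growth_records=growth_records,
    )


def log(message: str) -> None:
    print(message, file=sys.stderr)
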