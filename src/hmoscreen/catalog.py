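"""Curated HMO-utilization gene catalog: loading, validation, indexing.

The catalog holds nucleotide query genes (the screen is nucleotide-level
throughout), their grouping into functional loci (ABC-transporter clusters,
fucosyllactose clusters, the lnp cluster carrying the modified Leloir
pathway, ...) and per-species expectations.

The shipped default catalog mirrors the gene rosters surveyed across
infant-associated bifidobacteria. Because the real query sequences are
referenced by accession in external repositories, :func:`default_catalog`
synthesizes deterministic stand-in sequences (seeded, substitution-related
where two variants of a gene exist). All counts, loci and rules are real;
only the nucleotide strings are synthetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FUNCTION_CLASSES = frozenset(
    {
        "GH2", "GH20", "GH29", "GH33", "GH42", "GH95", "GH112", "GH136",
        "GH151", "SBP", "permease", "ATP_binding", "regulator", "catabolic",
        "chaperone", "other",
    }
)
FL_CLADES = frozenset({"none", "FL1_IV", "FL2_I", "FL2_II", "FL2_III"})
GH_FAMILIES = frozenset(c for c in FUNCTION_CLASSES if c.startswith("GH"))

VALID_BASES = frozenset("ACGT")
MIN_GENE_LENGTH = 100

METADATA_COLUMNS = (
    "gene_id", "name", "source_species", "locus_id", "function_class",
    "fl_clade", "substrate_tags",
)

# Entropy constant for the deterministic synthetic sequences of the default
# catalog; changing it changes every shipped sequence, so it is frozen here.
_DEFAULT_CATALOG_ENTROPY = 0x1893


class CatalogError(ValueError):
    """Raised for malformed catalog inputs."""


@dataclass(frozen=True)
class QueryGene:
    """One nucleotide query gene of the screening catalog."""

    gene_id: str
    name: str
    source_species: str
    locus_id: str | None
    function_class: str
    fl_clade: str
    sequence: str
    substrate_tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.function_class not in FUNCTION_CLASSES:
            raise CatalogError(
                f"gene {self.gene_id}: unknown function_class "
                f"{self.function_class!r}"
            )
        if self.fl_clade not in FL_CLADES:
            raise CatalogError(
                f"gene {self.gene_id}: unknown fl_clade {self.fl_clade!r}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise CatalogError(
                f"gene {self.gene_id}: non-ACGT characters {sorted(bad)}"
            )
        if len(self.sequence) < MIN_GENE_LENGTH:
            raise CatalogError(
                f"gene {self.gene_id}: sequence shorter than "
                f"{MIN_GENE_LENGTH} nt"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Locus:
    """A functional gene cluster with completeness and variant rules."""

    locus_id: str
    member_gene_ids: tuple[str, ...]
    required_for_complete: tuple[str, ...]
    required_for_functional: tuple[str, ...]
    variant_refs: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = set(self.member_gene_ids)
        if not set(self.required_for_functional) <= members:
            raise CatalogError(
                f"locus {self.locus_id}: required_for_functional not a "
                "subset of members"
            )
        seen: set[str] = set()
        for label, refs in self.variant_refs.items():
            if not refs:
                raise CatalogError(
                    f"locus {self.locus_id}: empty variant list {label!r}"
                )
            if seen & set(refs):
                raise CatalogError(
                    f"locus {self.locus_id}: variant lists overlap"
                )
            seen |= set(refs)


@dataclass(frozen=True)
class Catalog:
    genes: Mapping[str, QueryGene]
    loci: Mapping[str, Locus]
    species_expectations: Mapping[str, tuple[str, ...]] = field(
        default_factory=dict
    )

    @property
    def gene_order(self) -> tuple[str, ...]:
        return tuple(self.genes)

    def genes_in_family(self, family: str) -> tuple[str, ...]:
        return tuple(
            g.gene_id for g in self.genes.values()
            if g.function_class == family
        )

    def gh_families(self) -> tuple[str, ...]:
        fams = sorted(
            {g.function_class for g in self.genes.values()
             if g.function_class in GH_FAMILIES},
            key=lambda f: int(f[2:]),
        )
        return tuple(fams)


def _parse_locus_config(raw: Mapping) -> tuple[dict[str, Locus], dict]:
    loci: dict[str, Locus] = {}
    for locus_id, cfg in (raw.get("loci") or {}).items():
        members = tuple(cfg["members"])
        req_c = tuple(cfg.get("required_for_complete", members))
        req_f = tuple(cfg.get("required_for_functional", members))
        variants = {
            label: tuple(refs)
            for label, refs in (cfg.get("variant_refs") or {}).items()
        }
        loci[locus_id] = Locus(locus_id, members, req_c, req_f, variants)
    expectations = {
        sp: tuple(ids)
        for sp, ids in (raw.get("species_expectations") or {}).items()
    }
    return loci, expectations


def _read_locus_config(path: str | Path) -> Mapping:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_catalog(
    gene_fasta: str | Path,
    metadata_tsv: str | Path,
    locus_config: str | Path,
) -> Catalog:
    """Load and cross-reference a catalog from FASTA + TSV + YAML/JSON.

    Raises :class:`CatalogError` naming the offending gene for missing
    sequences, duplicate ids or malformed fields.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(gene_fasta), "fasta"):
        if rec.id in seqs:
            raise CatalogError(f"duplicate gene_id {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq)

    meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str).fillna("")
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise CatalogError(f"metadata missing columns {sorted(missing_cols)}")
    if meta["gene_id"].duplicated().any():
        dup = meta.loc[meta["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise CatalogError(f"duplicate gene_id {dup!r} in metadata")

    genes: dict[str, QueryGene] = {}
    for row in meta.itertuples(index=False):
        gid = row.gene_id
        if gid not in seqs:
            raise CatalogError(f"no FASTA record for gene_id {gid!r}")
        tags = frozenset(t for t in row.substrate_tags.split(";") if t)
        genes[gid] = QueryGene(
            gene_id=gid,
            name=row.name,
            source_species=row.source_species,
            locus_id=row.locus_id or None,
            function_class=row.function_class,
            fl_clade=row.fl_clade or "none",
            sequence=seqs[gid],
            substrate_tags=tags,
        )
    orphan = set(seqs) - set(genes)
    if orphan:
        raise CatalogError(
            f"FASTA records without metadata: {sorted(orphan)}"
        )

    loci, expectations = _parse_locus_config(_read_locus_config(locus_config))
    catalog = Catalog(genes=genes, loci=loci,
                      species_expectations=expectations)
    issues = validate_catalog(catalog)
    if issues:
        raise CatalogError("invalid catalog: " + "; ".join(issues))
    return catalog


def validate_catalog(catalog: Catalog) -> list[str]:
    """Return deterministic, ordered issue strings; [] iff well-formed."""
    issues: list[str] = []
    for gid in sorted(catalog.genes):
        gene = catalog.genes[gid]
        if gene.fl_clade != "none" and gene.function_class != "SBP":
            issues.append(
                f"gene {gid}: fl_clade {gene.fl_clade} on non-SBP "
                f"({gene.function_class})"
            )
        if gene.locus_id is not None and gene.locus_id not in catalog.loci:
            issues.append(f"gene {gid}: unknown locus {gene.locus_id!r}")
    for lid in sorted(catalog.loci):
        locus = catalog.loci[lid]
        for member in locus.member_gene_ids:
            if member not in catalog.genes:
                issues.append(f"locus {lid}: unknown member gene {member!r}")
        for ref in (r for refs in locus.variant_refs.values() for r in refs):
            if ref not in catalog.genes:
                issues.append(f"locus {lid}: unknown variant ref {ref!r}")
        for req in locus.required_for_complete:
            if req not in locus.member_gene_ids:
                issues.append(
                    f"locus {lid}: required_for_complete gene {req!r} "
                    "not a member"
                )
    for sp in sorted(catalog.species_expectations):
        for ident in catalog.species_expectations[sp]:
            if ident not in catalog.genes and ident not in catalog.loci:
                issues.append(
                    f"species {sp}: expectation {ident!r} resolves to "
                    "neither gene nor locus"
                )
    return issues


def write_catalog(
    catalog: Catalog,
    gene_fasta: str | Path,
    metadata_tsv: str | Path,
    locus_config: str | Path,
) -> None:
    """Serialize a catalog to the same three files `load_catalog` reads.

    Files written from the default catalog contain synthetic stand-in
    sequences; the FASTA description says so.
    """
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id,
                  description="synthetic stand-in query")
        for g in catalog.genes.values()
    ]
    SeqIO.write(records, str(gene_fasta), "fasta")

    rows = [
        {
            "gene_id": g.gene_id,
            "name": g.name,
            "source_species": g.source_species,
            "locus_id": g.locus_id or "",
            "function_class": g.function_class,
            "fl_clade": g.fl_clade,
            "substrate_tags": ";".join(sorted(g.substrate_tags)),
        }
        for g in catalog.genes.values()
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        metadata_tsv, sep="\t", index=False
    )

    cfg = {
        "loci": {
            lid: {
                "members": list(l.member_gene_ids),
                "required_for_complete": list(l.required_for_complete),
                "required_for_functional": list(l.required_for_functional),
                **(
                    {"variant_refs":
                     {k: list(v) for k, v in l.variant_refs.items()}}
                    if l.variant_refs else {}
                ),
            }
            for lid, l in catalog.loci.items()
        },
        "species_expectations": {
            sp: list(ids)
            for sp, ids in catalog.species_expectations.items()
        },
    }
    Path(locus_config).write_text(yaml.safe_dump(cfg, sort_keys=False))


# --------------------------------------------------------------------------
# default (shipped) catalog
# --------------------------------------------------------------------------

_CLASS_LENGTHS = {
    "GH2": 960, "GH20": 900, "GH29": 840, "GH33": 870, "GH42": 920,
    "GH95": 880, "GH112": 780, "GH136": 960, "GH151": 820,
    "SBP": 900, "permease": 660, "ATP_binding": 560, "regulator": 500,
    "catabolic": 620, "chaperone": 460, "other": 520,
}

# gene pairs shipped as diverged variants of one ancestral sequence:
# (variant gene, ancestor gene, percent identity to ancestor)
_VARIANT_DERIVATIONS = (
    ("gltA_adult", "gltA", 99.0),
    ("gltB_adult", "gltB", 99.0),
    ("gltC_adult", "gltC", 99.0),
    ("gltA_infant", "gltA", 93.0),
    ("gltB_infant", "gltB", 93.0),
    ("gltC_infant", "gltC", 93.0),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _synthesize_sequence(length: int, rng: np.random.Generator,
                         gc: float = 0.60) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def _substitute(sequence: str, identity_pct: float,
                rng: np.random.Generator) -> str:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < (100.0 - identity_pct) / 100.0
    if hit.any():
        codes = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode("ascii")


def default_catalog() -> Catalog:
    """The shipped catalog with deterministic synthetic stand-in sequences.

    Sequences are generated once per process from a frozen seed: unrelated
    genes are independent random sequences, while the adult/infant gltABC
    transporter variants are derived from a shared ancestor at 99% and 93%
    nucleotide identity so that variant typing has a real signal to recover.
    """
    data = resources.files("hmoscreen.data")
    meta = pd.read_csv(
        data / "default_gene_metadata.tsv", sep="\t", dtype=str
    ).fillna("")
    raw_cfg = yaml.safe_load((data / "default_loci.yaml").read_text())
    loci, expectations = _parse_locus_config(raw_cfg)

    derived = {v: (anc, ident) for v, anc, ident in _VARIANT_DERIVATIONS}
    seqs: dict[str, str] = {}
    for i, row in enumerate(meta.itertuples(index=False)):
        gid = row.gene_id
        rng = np.random.default_rng(
            np.random.SeedSequence(_DEFAULT_CATALOG_ENTROPY, spawn_key=(i,))
        )
        if gid in derived:
            anc, ident = derived[gid]
            seqs[gid] = _substitute(seqs[anc], ident, rng)
        else:
            seqs[gid] = _synthesize_sequence(
                _CLASS_LENGTHS[row.function_class], rng
            )

    genes = {
        row.gene_id: QueryGene(
            gene_id=row.gene_id,
            name=row.name,
            source_species=row.source_species,
            locus_id=row.locus_id or None,
            function_class=row.function_class,
            fl_clade=row.fl_clade or "none",
            sequence=seqs[row.gene_id],
            substrate_tags=frozenset(
                t for t in row.substrate_tags.split(";") if t
            ),
        )
        for row in meta.itertuples(index=False)
    }
    catalog = Catalog(genes=genes, loci=loci,
                      species_expectations=expectations)
    issues = validate_catalog(catalog)
    if issues:  # pragma: no cover - shipped data must be clean
        raise CatalogError("shipped catalog invalid: " + "; ".join(issues))
    return catalog


def subset_catalog(catalog: Catalog, gene_ids: Iterable[str]) -> Catalog:
    """Restrict a catalog to a subset of genes (loci filtered to survivors)."""
    keep = [g for g in catalog.gene_order if g in set(gene_ids)]
    genes = {g: catalog.genes[g] for g in keep}
    loci = {}
    for lid, locus in catalog.loci.items():
        members = tuple(m for m in locus.member_gene_ids if m in genes)
        if not members:
            continue
        loci[lid] = replace(
            locus,
            member_gene_ids=members,
            required_for_complete=tuple(
                m for m in locus.required_for_complete if m in genes
            ),
            required_for_functional=tuple(
                m for m in locus.required_for_functional if m in genes
            ),
            variant_refs={
                lab: tuple(r for r in refs if r in genes)
                for lab, refs in locus.variant_refs.items()
                if any(r in genes for r in refs)
            },
        )
    return Catalog(genes=genes, loci=loci, species_expectations={})
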