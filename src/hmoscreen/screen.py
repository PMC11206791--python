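"""Genome screening: seed-and-extend homology search and presence calls.

Each catalog gene is searched against every contig on both strands; the
best local alignments are reported with percent identity (matches over
alignment columns, gap columns included) and query coverage (aligned query
span over query length). Presence is called at strict thresholds
(identity > 50 AND coverage > 50 by default). A hit whose net indel length
is not a multiple of three is flagged as frame-disrupting.

Two search modes:

* exhaustive - optimal local alignment over every contig x strand, one hit
  per contig/strand; the top hit is the global optimum.
* seeded (default) - k-mer seeding plus an ungapped diagonal filter, with
  the exact affine DP run only inside candidate windows. Agrees with
  exhaustive search on homologs down to ~70% identity at the default k.

The minus strand is handled by aligning the reverse-complemented query to
the forward contig, so target coordinates are always forward-strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import (
    Alignment,
    AlignmentError,
    DEFAULT_SCORING,
    ScoringScheme,
    encode,
    local_align,
    max_subarray_score,
    reverse_complement,
)
from .catalog import Catalog, GH_FAMILIES, QueryGene

DEFAULT_SEED_K = 11
#: minimum ungapped diagonal (Kadane) score for a seed band to be extended
MIN_CHAIN_SCORE = 60


@dataclass(frozen=True)
class HitRecord:
    """Best local-alignment hit of a query gene on a contig."""

    query_id: str
    contig_id: str
    strand: str  # "+" or "-"
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    align_cols: int
    identity_pct: float
    coverage_pct: float
    score: int
    inserted_bases: int
    deleted_bases: int

    @property
    def net_indel_mod3(self) -> int:
        return (self.inserted_bases - self.deleted_bases) % 3


@dataclass(frozen=True)
class PresenceCall:
    query_id: str
    present: bool
    best_hit: HitRecord | None
    identity_min: float
    coverage_min: float
    strict: bool


def frame_disruption(hit: HitRecord) -> bool:
    """True iff the hit's net indel length within the aligned region is not
    a multiple of 3 (proxy for a frameshift-disrupted coding sequence)."""
    return hit.net_indel_mod3 != 0


def _hit_from_alignment(
    aln: Alignment, query_id: str, contig_id: str, strand: str,
    query_length: int, t_offset: int = 0,
) -> HitRecord:
    q_start, q_end = aln.q_start, aln.q_end
    if strand == "-":
        # alignment used the reverse-complemented query; map back
        q_start, q_end = query_length - aln.q_end, query_length - aln.q_start
    return HitRecord(
        query_id=query_id,
        contig_id=contig_id,
        strand=strand,
        q_start=q_start,
        q_end=q_end,
        t_start=aln.t_start + t_offset,
        t_end=aln.t_end + t_offset,
        matches=aln.matches,
        align_cols=aln.align_cols,
        identity_pct=aln.identity_pct,
        coverage_pct=aln.coverage_pct(query_length),
        score=aln.score,
        inserted_bases=aln.inserted_bases,
        deleted_bases=aln.deleted_bases,
    )


class GenomeIndex:
    """Per-genome k-mer index shared across queries and strands."""

    def __init__(self, contigs: Sequence[tuple[str, str]], k: int = DEFAULT_SEED_K):
        if not contigs:
            raise ValueError("genome has no contigs")
        if k < 8:
            raise ValueError("seed_k must be >= 8")
        self.k = k
        self.contigs: list[tuple[str, np.ndarray]] = []
        self._index: list[dict[bytes, list[int]]] = []
        for contig_id, seq in contigs:
            try:
                arr = encode(seq)
            except AlignmentError as exc:
                raise AlignmentError(
                    f"contig {contig_id!r}: {exc}"
                ) from None
            self.contigs.append((contig_id, arr))
            idx: dict[bytes, list[int]] = defaultdict(list)
            data = arr.tobytes()
            for pos in range(len(data) - k + 1):
                idx[data[pos:pos + k]].append(pos)
            self._index.append(dict(idx))

    def seed_positions(self, query_arr: np.ndarray, contig_i: int
                       ) -> list[tuple[int, int]]:
        """(query_pos, target_pos) pairs of exact k-mer matches."""
        k = self.k
        idx = self._index[contig_i]
        data = query_arr.tobytes()
        out: list[tuple[int, int]] = []
        for qp in range(len(data) - k + 1):
            hits = idx.get(data[qp:qp + k])
            if hits:
                out.extend((qp, tp) for tp in hits)
        return out


def _candidate_windows(
    seeds: list[tuple[int, int]], m: int, n: int,
    q: np.ndarray, t: np.ndarray, sc: ScoringScheme,
    min_chain_score: int,
) -> list[tuple[int, int]]:
    """Diagonal-filtered seed bands merged into target windows for exact DP."""
    diagonals = sorted({tp - qp for qp, tp in seeds})
    intervals: list[tuple[int, int]] = []
    last_kept = None
    for d in diagonals:
        if last_kept is not None and d - last_kept < 16:
            continue  # same band, already scored
        ts = max(d, 0)
        qs = ts - d
        span = min(m - qs, n - ts)
        if span <= 0:
            continue
        equal = q[qs:qs + span] == t[ts:ts + span]
        if max_subarray_score(equal, sc) >= min_chain_score:
            intervals.append((max(0, d), min(n, d + m)))
            last_kept = d
    if not intervals:
        return []
    intervals.sort()
    merged = [intervals[0]]
    for a, b in intervals[1:]:
        if a <= merged[-1][1] + 32:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    # pad so gapped alignments can extend past the seeded diagonal
    pad = m
    return [(max(0, a - pad), min(n, b + pad)) for a, b in merged]


def search_genome(
    gene: QueryGene | tuple[str, str],
    genome: Sequence[tuple[str, str]] | GenomeIndex,
    scoring: ScoringScheme = DEFAULT_SCORING,
    seed_k: int = DEFAULT_SEED_K,
    exhaustive: bool = False,
    min_chain_score: int = MIN_CHAIN_SCORE,
) -> list[HitRecord]:
    """Search one query gene against a genome, both strands.

    ``genome`` may be a list of (contig_id, sequence) pairs or a prebuilt
    :class:`GenomeIndex` (reuse the index when screening many genes).
    Returns hits sorted by descending score, then contig id and position.
    """
    if isinstance(gene, QueryGene):
        query_id, query_seq = gene.gene_id, gene.sequence
    else:
        query_id, query_seq = gene
    m = len(query_seq)
    strands = {"+": encode(query_seq), "-": encode(reverse_complement(query_seq))}

    hits: list[HitRecord] = []
    if exhaustive:
        contigs = (
            genome.contigs if isinstance(genome, GenomeIndex)
            else [(cid, encode(seq)) for cid, seq in genome]
        )
        for contig_id, t in contigs:
            for strand, q in strands.items():
                aln = local_align(q, t, scoring)
                if aln.score > 0:
                    hits.append(_hit_from_alignment(
                        aln, query_id, contig_id, strand, m))
    else:
        index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(
            genome, k=seed_k)
        for ci, (contig_id, t) in enumerate(index.contigs):
            for strand, q in strands.items():
                seeds = index.seed_positions(q, ci)
                if not seeds:
                    continue
                windows = _candidate_windows(
                    seeds, m, t.size, q, t, scoring, min_chain_score)
                for a, b in windows:
                    aln = local_align(q, t[a:b], scoring)
                    if aln.score > 0:
                        hits.append(_hit_from_alignment(
                            aln, query_id, contig_id, strand, m, t_offset=a))
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.t_start, h.strand))
    return hits


def call_presence(
    hits: Sequence[HitRecord],
    identity_min: float = 50.0,
    coverage_min: float = 50.0,
    strict: bool = True,
    query_id: str | None = None,
) -> PresenceCall:
    """Threshold the best hit into a presence decision.

    ``strict`` uses the strict inequalities (identity > identity_min AND
    coverage > coverage_min); ``strict=False`` uses >= for sensitivity
    analyses. The reported best hit is the highest-scoring *qualifying* hit
    when one exists, else the highest-scoring hit overall.
    """
    for thr in (identity_min, coverage_min):
        if not 0 <= thr <= 100:
            raise ValueError("thresholds must be within [0, 100]")

    def qualifies(h: HitRecord) -> bool:
        if strict:
            return h.identity_pct > identity_min and h.coverage_pct > coverage_min
        return h.identity_pct >= identity_min and h.coverage_pct >= coverage_min

    qid = query_id or (hits[0].query_id if hits else "")
    qualifying = [h for h in hits if qualifies(h)]
    pool = qualifying or list(hits)
    best = max(pool, key=lambda h: h.score) if pool else None
    return PresenceCall(
        query_id=qid,
        present=bool(qualifying),
        best_hit=best,
        identity_min=identity_min,
        coverage_min=coverage_min,
        strict=strict,
    )


def screen_genome(
    catalog: Catalog,
    genome: Sequence[tuple[str, str]],
    gene_ids: Iterable[str] | None = None,
    scoring: ScoringScheme = DEFAULT_SCORING,
    seed_k: int = DEFAULT_SEED_K,
    exhaustive: bool = False,
    identity_min: float = 50.0,
    coverage_min: float = 50.0,
    strict: bool = True,
) -> tuple[dict[str, list[HitRecord]], dict[str, PresenceCall]]:
    """Screen many catalog genes against one genome; returns
    (hits per gene, presence call per gene)."""
    ids = list(gene_ids) if gene_ids is not None else list(catalog.gene_order)
    index = None if exhaustive else GenomeIndex(genome, k=seed_k)
    hits_by_gene: dict[str, list[HitRecord]] = {}
    calls: dict[str, PresenceCall] = {}
    for gid in ids:
        gene = catalog.genes[gid]
        hits = search_genome(
            gene, index if index is not None else genome,
            scoring=scoring, seed_k=seed_k, exhaustive=exhaustive,
        )
        hits_by_gene[gid] = hits
        calls[gid] = call_presence(
            hits, identity_min, coverage_min, strict, query_id=gid)
    return hits_by_gene, calls


def gh_family_counts(
    calls: Mapping[str, PresenceCall], catalog: Catalog
) -> dict[str, int]:
    """Count present genes per GH family (the catalog-restricted analogue of
    a genome-wide GH annotation); families with no present member report 0."""
    counts = {fam: 0 for fam in catalog.gh_families()}
    for gid, call in calls.items():
        fam = catalog.genes[gid].function_class
        if call.present and fam in GH_FAMILIES:
            counts[fam] = counts.get(fam, 0) + 1
    return counts
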