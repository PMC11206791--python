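# Methods

This note documents the models, conventions and design choices behind
`hmoscreen`, in the order the pipeline applies them.

## Homology screen

**Alignment model.** Presence calling rests on optimal local alignment
with integer match/mismatch scores and affine gap costs (Gotoh
three-state recurrence). The gap convention is: a gap of length *L* costs
`gap_open + (L-1) * gap_extend`, with `gap_open <= gap_extend < 0`. The
engine computes exact optima: rows are vectorized in NumPy, horizontal
gap states are resolved in closed form via a prefix-maximum (the
open-from-gap case is dominated because `gap_open <= gap_extend`), and for
targets longer than 8 kb the optimal end cell is located by a
linear-memory scoring scan with the traceback recovered inside a window
whose size provably bounds the target span of any positive-scoring
alignment (`|q| + |q| * match/|gap_extend|` columns). Tests verify score
equality against an independently written brute-force triple-matrix DP on
hundreds of seeded random pairs and against Biopython's PairwiseAligner.

**Scoring presets.** The default is blastn-like (`+2/-3/-5/-2`). Under
these scores the expected per-column score turns negative below ~60%
identity, so alignments to distant homologs clip to high-identity
islands — exactly like the BLAST-style screens this engine replaces. For
work near the 50% presence threshold a *sensitive* preset (`+2/-1/-5/-2`)
keeps the expected score positive down to ~34% identity, letting
borderline homologs extend over the full query; the threshold-boundary
acceptance checks use it for the identity-side plants. Both presets are
plain `ScoringScheme` values and user-replaceable.

**Search modes.** Exhaustive mode aligns every contig × strand optimally.
The default seeded mode indexes contig k-mers (k = 11), groups seed
matches by diagonal, scores each band ungapped (Kadane maximum-segment
score; bands below 60 are discarded — random 11-mer hits score ~22, true
homologs ≥ 70% identity score in the hundreds), merges surviving bands
into windows padded by one query length, and runs the exact aligner only
there. Seeded and exhaustive searches agree on planted homologs down to
~70% identity (tested); genuinely borderline (<60% identity) queries
should use `exhaustive=True`. Minus-strand searching aligns the
reverse-complemented query against the forward contig, so reported target
coordinates are always forward-strand, 0-based, half-open.

**Presence thresholds.** present iff identity > 50 AND coverage > 50
(strict, matching the screen convention this pipeline reproduces); a flag
switches to `>=` for sensitivity analyses. Coverage is computed from the
single best local alignment — no HSP merging; a fragmented gene whose best
single alignment covers ≤50% of the query is called absent by design.
When qualifying and non-qualifying hits coexist, the reported best hit is
the highest-scoring *qualifying* one.

**Tie-breaking.** Equal-score optima resolve to the lowest alignment end
on the target, then the lowest end on the query, with a
diagonal-preferring traceback. This is a determinism guarantee, not a
biological claim.

**Frame disruption.** A hit is flagged when
`(inserted_bases - deleted_bases) mod 3 != 0` within the aligned region —
a 17-nt insertion flags, a 3-nt indel does not. Flagged genes still count
as *present* (the sequence is there) but break the `functional` flag of
any locus that requires them, mirroring a detectable but likely
pseudogenized copy.

## Catalog

The catalog is nucleotide-only (the screen it models is a nucleotide
screen; protein search is out of scope). Genes carry a function class
(GH families, SBP, permease, ATP-binding, regulator, catabolic,
chaperone), optional FL-transporter clade (only meaningful on SBPs), and
locus membership. Locus completeness defaults to *all members present*;
`required_for_functional` isolates the transporter-critical subset (e.g.
the FL ABC transporter inside the fucosyllactose cluster: fucosidases plus
catabolism without the transporter is a partial, non-functional cluster).
The lnp locus ships with adult/infant gltABC variant reference genes;
variant typing assigns the label with the higher mean best-hit identity
across its references, with a 1-point margin below which the call is
"ambiguous" — the margin is an artifact choice, since assignment "by
homolog similarity" is otherwise underspecified.

Because the real query sequences live behind repository accessions, the
shipped catalog's nucleotide strings are deterministic synthetic
stand-ins (seeded per gene): unrelated genes are independent random
sequences; the adult/infant transporter variants derive from one ancestor
at 99% / 93% identity so variant typing has a real signal. All rosters,
locus definitions and rules are real; only the letters are synthetic — a
user with the real sequences supplies their own FASTA/TSV/YAML via
`load_catalog`.

## Configuration groups

*B. infantis* strains are grouped from locus calls only: I — gltABC
intact; II — gltABC lost, nahS lost, fucosyllactose cluster 3 retained,
H2 complete; III — gltABC, nahS and cluster 3 all lost; IV — gltABC and
cluster 3 lost, nahS retained, H2 partial. "Partially H2" is
operationalized as locus state = partial without naming specific genes.
Patterns matching no group return "unclassified" rather than a
nearest-neighbour guess.

## Phenotype rules

Rules are data (YAML), not code: species-scoped, priority-ordered boolean
predicates over gene presence, locus state/functionality, FL clades and
GH families. The highest-priority satisfied rule wins per (species,
substrate); equal-priority conflicts are configuration errors; an
always-true no-growth fallback closes every substrate. The shipped
default encodes, per species, the import routes (gltABC, nahS, the
LNB/LNT cluster, the FL clusters with clade-dependent substrate range and
the per-species GH95→3FL cross-reactivity) and the extracellular
strategies (lnbX/lnbY; the *B. bifidum* membrane-bound GH set, which alone
predicts sialyllactose growth — an intracellular GH33 without a transporter
predicts none). All shipped growth predicates are negation-free, so
predictions are monotone: losing a gene can only remove predicted growth
(property-tested). Observed-but-unexplained phenotypes (e.g. growth on
3FL without any identifiable FL transporter) are deliberately *not*
encoded; on real data they surface as discordance, which is the honest
output. Sequence-level activity loss (a full-length sialidase without
enzymatic activity) is invisible to a presence screen and likewise
surfaces as discordance.

## Growth tables

Endpoint OD600 only, median across replicates (robust to one failed
well), blank-subtracted by default (configurable off; whether the
original assay subtracted is not documented, so subtraction is the
package's choice). Categories: none < 0.4 ≤ moderate < 1.0 ≤ good. These
cut-offs are artifact-defined: they separate the printed group means of
the reference assay (~0.32 non-growing, ~0.70 moderate, ~1.16 good) and
are not claimed to generalize to other media or readers. Negative deltas
clamp to zero with a warning.

## Cohort statistics

Prevalence reports the exact fraction and a round-half-up integer percent
(the convention of the prevalence tables this mirrors). Conservation is
the mean ± sample SD (n−1) of best-hit identity over carriers; a single
carrier reports SD 0 with an explicit flag. Group growth comparisons use
Welch's unequal-variance t with Welch–Satterthwaite df; the test type is
an assumption — the reference analysis never names its test. Both
strain-level (default) and replicate-level comparisons are supported:
printed p-values of the order 1e-3 on small strain groups are only
reachable at replicate level, so the acceptance script reports the
replicate-level p for the cluster contrast. No multiple-testing
correction by default (raw p-values are reported); Bonferroni is a flag
away in user code. Concordance counts TP/FP/FN/TN per substrate with
growth-call = category ≠ none.

## Synthetic cohorts

**What it emulates.** Per-species GC (55.9–64.8%, mean ~59.8) and
genotype architectures of a 130-strain, 10-species reference cohort:
carrier counts (43/67 lnbX with 100% lnbY co-occurrence, 47/67 adult-type
gltABC arranged so the lnbX-by-variant split lands at 68%/55%, 51/67
Bga2A, 5/13 Bga42A in *B. adolescentis*, 4/8 LNB/LNT-cluster carriers in
*B. catenulatum*, one FHMO carrier among 5 *B. pseudocatenulatum*), the
four *B. infantis* configuration groups, the *B. bifidum* extracellular
set at a tight identity distribution (stratified normal quantiles around
99.1 ± 0.6%) with one 17-nt lnpA frameshift strain, and growth plates
anchored to the printed group means (good ≈ 1.15, moderate 0.70, the
lnbX± LNT means 1.16/0.89, the cluster− baseline 0.32; the generic
no-growth baseline 0.10 is an artifact choice inside the none band).
Replicate noise defaults to 0.05 OD (typical triplicate scatter) and to
0.14 OD for the *B. catenulatum* template, matching that contrast's
printed dispersion.

**What it does not emulate.** Real intergenic composition, operon
structure, assembly artifacts, HSP fragmentation across contig breaks
(plants are never split), indel divergence (substitution-only, so
realized identity is binomially concentrated at the target; the
frameshift insertion is the one exception), and unexplained phenotypes.
Passing the closed loop therefore shows the pipeline's stages are
mutually consistent and exact on recoverable signal — not that the rule
set is complete for wild strains.

**Scale.** Genome length is a template parameter: 200 kb per strain is
the package's cohort-scale default (used for the 67-strain recovery run),
60–80 kb for the multi-species panels. These desk-scale backgrounds keep
k-mer statistics realistic (a 200 kb background yields a handful of random
11-mer seed hits per gene, exercising the chain filter) while staying fast.
Results are driven by planted signal, not background length.

**Seeding.** One integer seed per simulation; per-strain and plate
streams are spawned from it (`SeedSequence.spawn`), so identical configs
reproduce identical FASTA bytes and plate values. Template-level carrier
assignments are deterministic (first-k-strains conventions documented in
the docstrings); per-gene identity jitter uses fixed template seeds so
the *conditions* are stable while `--seed` varies the realized genomes.

## Known limitations

- Single-HSP coverage understates fragmented or contig-spanning genes.
- The seeded search can miss homologs below ~60–65% identity under the
  default scoring; use exhaustive mode plus the sensitive preset there.
- Variant typing assumes variants are distinguishable by mean identity
  (≥1 point apart); recombinant loci type as "ambiguous".
- Rules are binary growth/no-growth; growth magnitude lives entirely in
  the OD categories, and regulatory effects (response times, sequential
  preferences) are out of scope.
- The shipped catalog's sequences are synthetic stand-ins: real-data use
  requires supplying real query sequences with the same metadata schema.
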