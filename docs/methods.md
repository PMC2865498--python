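# Methods

`degradomics` annotates the protease repertoire (the *degradome*) of a
genome by iterative translated homology search against a curated seed
set, then compares repertoires across species. Because the interesting
behaviour of such a pipeline — does it recover tandem duplications,
expansions, losses, and catalytically dead copies? — can only be judged
against known truth, the package includes a first-class synthetic-genome
generator and evaluates itself end to end on forged data.

## The synthetic genome forge (`seqforge`)

`forge_genome` implants multi-exon protein-coding genes into i.i.d.
uniform random intergenic background. The event menu mirrors what a
cross-species degradome comparison must detect: tandem duplication
(adjacent copies on one contig), dispersed duplication/expansion (each
copy on its own contig), loss (a family simply not planned for a
species), and pseudogenization, either by substituting every catalytic
residue (`catalytic_substitution`) or by writing a stop codon mid-exon
(`inframe_stop`).

Divergence model. For each species x family, a shared ancestor protein
is drawn at *divergence/2* from the seed and every copy diverges a
further *divergence/2* from that ancestor. The shared component matters:
independent divergence of each copy from the seed would make within-
species duplicates equidistant from every other species' copy (a star
phylogeny), and no tree method could recover a duplicate pair as
sisters. Post-speciation duplicates share their lineage's substitutions,
and the forge reproduces that.

Parameters that matter, with defaults and reasons:

| parameter | default | why |
|---|---|---|
| `divergence` | 0.15 | per-copy expected substituted fraction; mid-range protein identity (~85%) where detection is comfortable but non-trivial |
| `n_exons` | 3 | exercises chaining and splice tuning without dominating runtime |
| exon size | >= 30 codons | shorter exons score below any sensible E-value cutoff in a translated search of this scale, so the forge does not emit what the method could never see |
| `intron_length` | 60-400 nt | >= 20 enforced; GT...AG termini always |
| `intergenic_length` | 6-12 kb | genes must sit further apart than `max_intron` (5 kb) or single-linkage HSP clustering would merge neighbouring loci; 6-12 kb also matches the separation scale of real tandem protease pairs |

Simplifications, deliberately: substitutions only (no indels), so
catalytic-position bookkeeping is exact; uniform residue substitution
(not BLOSUM-biased); uniform codon choice; phase-0 introns only
(inserted at codon boundaries); uniform base composition. Consequently a
green test suite says the pipeline's *logic* is right under clean
sequence statistics — it says nothing about repeat content, GC
structure, frameshifts, alternative splicing, or assembly artefacts in
real genomes.

## Translated search (`transearch`)

A TBLASTN-style engine: exact six-frame translation with coordinate maps
back to forward-strand nucleotides ('N'-containing codons translate to
'X', which scores 0 against everything), word seeding (k = 4, BLOSUM62
word score >= 13, exact matches always qualify), ungapped X-drop
extension, then banded affine-gap X-drop extension (gaps 11/1, X = 20,
band 10). Stop codons in the subject bound every extension: an HSP never
spans a '*'. E-values follow Karlin-Altschul, `E = K * m * n *
exp(-lambda * S)` with *n* the total translated length searched; no
edge-effect length correction is applied.

Two staging heuristics keep the pure-Python engine fast and are config
keys, not contracts: a seed must have word + flanking-word diagonal
context >= 18 (`context_threshold`) before any extension, and the gapped
pass only triggers once the ungapped extension reaches 25
(`ungapped_trigger`), well below the 40-point reporting floor so no
reportable HSP on substitution-only data can be lost. Seeds falling
inside an already-extended region of the same diagonal neighbourhood are
skipped, as in BLAST.

E-value calibration. The shipped defaults lambda = 0.32, K = 0.066 were
fitted with `calibrate_evalue_params`: shuffled queries are searched
against random genomes and a log-linear fit of HSP-score exceedance
counts recovers both parameters. Stock gapped BLOSUM62/11/1 values
(0.267 / 0.041) overpredict this engine's null roughly tenfold, because
translated random DNA is segmented by stop codons every ~21 residues and
alignments cannot cross them; fitting the engine's own null is the same
empirical route BLAST takes for its gapped parameters. The stock values
remain one config assignment away.

## Annotation (`bati`)

The Blast-Annotate-Tune-Iterate loop.

*Cluster*: single-linkage over HSPs on one contig and strand with
genomic gaps <= `max_intron` (default 5 kb — matched to the forge's
intron plan; real vertebrate introns would need much more).

*Chain*: per query, the maximum-score chain of HSPs colinear in query
and (coding-strand) genome coordinates, genome overlaps forbidden.
Query overlaps between consecutive HSPs are the norm, not the exception:
X-drop extensions routinely overshoot an exon boundary 10-25 residues
into intron translation, because chance-positive tails survive an
X-drop of 20. An overlap is therefore resolved by its optimal split —
trim `o1` residues from the upstream HSP's right and `o2 = overlap - o1`
from the downstream's left, choosing the split that retains the most
score. The DP state is (HSP, left-trim), so a short middle HSP can never
be trimmed past its length by its two neighbouring junctions. The chain
penalty is exactly the trimmed columns' score, so the reported chain
score always equals the sum of member scores minus penalties.

*Tune*: each internal junction may shift its donor/acceptor pair by up
to `tune_window` (default 30 nt) onto GT...AG, with the two shifts equal
mod 3 so the reading frame survives. Candidate pairs are ranked by the
BLOSUM score of the re-translated seam against the query residues it
should encode (chain trims keep query coverage contiguous, so the seam's
query offset follows from cumulative coding length); displacement is
only the tie-break. Without protein-evidence ranking, the nearest
GT/AG pair regularly writes a premature stop into an otherwise intact
model. When no query is available, stop-free candidates are preferred
and nearest wins.

*Iterate*: intact predictions join the query set (inheriting the family
of their best-scoring supporting query) and the loop repeats until a
round contributes no new locus, or `max_iterations` (10). Models are
deduplicated at 50% reciprocal genomic overlap, keeping the higher
chain score; `iteration_found` records the earliest round each locus
appeared, and the locus set is non-decreasing across rounds by
construction.

`bgmix_report` merges every HSP from every query into one table sorted
by chromosomal location, flagging HSPs not covered by any final model —
the review surface for missed genes.

## Orthology and family status (`orthomap`)

Reciprocal best hits over global affine alignment scores (BLOSUM62,
11/1, via Biopython's PairwiseAligner). A pair is orthologous only if
each is the other's *unique* best by strictly more than `margin`
(default 0); exact ties fall into the conservative
`no_clear_orthologue` bucket, which is where large complex families
belong. Tandem groups are same-family models within `max_separation`
(1 Mb) on one contig; remaining multi-copy families count as dispersed.
Family status is a pure function of copy counts: 0 -> absent (or
`not_found` when more than 20% of the family's expected region is
assembly gap, if such a fraction is supplied), 1/2/3/4+ ->
present/duplicated/triplicated/expanded, and any copies with no intact
open reading frame -> pseudogene_only.

## Catalytic classification (`protclass`)

A candidate is aligned globally to its family's best-scoring seed; the
seed's catalytic positions (His-Asp-Ser triad for serine proteases,
His-Cys dyad for cysteine, paired Asp for aspartyl, zinc-binding
His-Glu-His for metallo) are read through the alignment. One
substituted or deleted catalytic residue already predicts loss of
proteolytic function, so the threshold is >= 1; conservative
substitutions (Ser -> Thr) get no exemption, by design, though callers
can relax the rule by supplying their own site comparison.

## Phylogenetics (`phylo`)

For families where orthology is ambiguous or copy number varies:
progressive alignment over a neighbor-joining guide tree (scikit-bio's
NJ on score-derived distances d = (S_aa + S_bb)/2 - S_ab, profiles
merged by vectorized affine DP, lexicographic tie-breaks so the result
is input-order independent); column bootstrap; Fitch small parsimony
with gaps/'X' as missing data (bit-mask columns, vectorized across the
alignment); exhaustive topology search up to 8 taxa (returning *all*
minimum-score trees), stepwise addition plus NNI descent beyond.
The NNI descent follows equal-score rearrangements too (parsimony
landscapes are plateau-ridden) within a deterministic 600-evaluation
budget; on forged 7-taxon families it recovers the exhaustive minimum
in >= 95% of replicates, though on signal-free noise it can stop short.

Consensus keeps exactly the bipartitions present in STRICTLY more than
`threshold` replicates (the ">50 of 100" display convention); a
replicate with k equally parsimonious trees contributes each bipartition
at weight 1/k. Genetic-code-aware parsimony costs are intentionally not
reproduced; plain Fitch is the oracle-checkable baseline. Outgroup
rooting requires the outgroup to be a clade and otherwise reports the
violating bipartition.

## Orchestration (`report`, `cli`)

One YAML config drives everything; all randomness flows from a single
master seed, and identical config + seed gives byte-identical GFF3,
TSV, FASTA, Newick, and manifest outputs (verified byte-for-byte in the
acceptance suite). The built-in demonstration plan forges three species
sharing twelve families: one tandem-duplicated in species A only, one
with seven dispersed copies in species A including a catalytic
knockout, one triplicated in A and B but single in C, two absent from A
and B, and seven stable singletons — at divergence 0.15. Stage logging
reports wall time and in/out counts; nothing time-dependent enters any
artifact. The `--threads` flag is accepted for interface stability;
results are independent of it.

Problem sizes used by the shipped evaluation: ~150-280 kb of genome per
species, 43 implanted loci, 100 bootstrap replicates per family tree,
200-replicate oracle batteries for chaining and seeding, 20 replicates
for ortholog-recovery and 10 for the duplication-sister property.

## Known limitations

- Substitution-only truth: frameshift-tolerant alignment and indel
  handling in chains are untested by design.
- The E-value model omits edge-effect length correction and assumes the
  engine-calibrated (lambda, K) transfer across desk-scale search sizes;
  both are documented biases, not guarantees.
- Terminal exons shorter than ~25 codons score below the default
  E-value cutoff and will be missed; boundary recovery beyond
  `tune_window` of the chained seam is not attempted.
- RBH margin 0 deliberately under-calls orthology in near-tie paralog
  situations; that is the intended conservative behaviour, not a bug.
- The heuristic tree search guarantees a local NNI optimum only.
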