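# Methods

## The generative model

A heavy-chain read is assembled left to right as

    V[0 : |V|-tV]  P?  N1  P?  D[t5 : |D|-t3]  P?  N2  P?  J[tJ : |J|]

and a kappa read as `V P? N1 P? J`.  Segments are drawn from configurable
usage distributions (uniform over functional segments by default); each
junction end is trimmed by a geometric number of bases (mean 2 by
default); an untrimmed end carries, with probability `p_prob` (default
0.5), a palindromic P extension of 1..3 bases — the reverse complement
of the terminal germline bases, the standard immunological convention,
since the quantity is measured in repertoire data but its generation is
not specified there; N inserts are uniform random bases with geometric
lengths (default mean 4 per junction, in the range reported for human
junctional additions).  Trimming never removes the CDR3 anchor codons
(Cys104 on V, Phe/Trp-118 on J) and always leaves at least one D base:
rearrangements that destroy the anchors would be unanalysable by any
CDR3-based pipeline and are vanishingly rare in annotated data.

SHM mutates each base independently with probability `shm_rate`
(default 0.01, a few mutations per ~300-nt variable region, typical of
an actively maturing repertoire), multiplied by `hotspot_multiplier`
(default 5) inside CDR positions to reproduce the CDR-concentrated
mutation pattern of antigen selection.  Clonal structure is a star:
`n_lineages` founder rearrangements, lineage sizes drawn from an
expansion distribution and apportioned (largest-remainder) to exactly
`n_reads`, every copy mutated independently from its founder.
Tree-structured within-lineage SHM is a non-goal; the star is sufficient
for position-profile and divergence statistics, which aggregate over
reads, not over phylogenies.

### Canonical junctions and identifiability

A junction decomposition is not identifiable in general: an N base that
happens to continue the adjacent germline segment, or to extend a
palindrome, cannot be distinguished from templated sequence by any
annotator.  With `identifiable=True` (default) the generator
rejection-samples junctions until the greedy maximal-germline /
maximal-P decomposition — the same convention the annotator applies —
reproduces the sampled truth.  Ground truth is then unique, and
"the annotator recovers truth exactly at zero SHM" is a meaningful,
testable statement.  The rejection slightly truncates the N and trim
distributions (it also keeps the retained D detectable); analyses that
quantify the raw generator distributions (parameter-recovery checks)
therefore use `identifiable=False`, where the truth fields are still
exact by construction.

### What the generator does not emulate

No sequencing error, paired-end merging, chimeras, indel SHM, isotype
sequence, allelic variation beyond what the reference contains, or
selection.  The last matters for interpretation: real repertoires are
>90% productive because nonproductive rearrangements are selected
against, while the simulator's junction arithmetic leaves only ~1/3 of
reads in frame (and fewer stop-free).  Passing tests therefore validate
the measurement machinery, not biological effect sizes.

## Annotation

Segment assignment is exact ungapped local alignment (match +1,
mismatch −1, no gaps), scanning every diagonal with a compiled Kadane
pass; a plain-Python implementation of the same scan is kept as the
test oracle.  V is chosen over all V of the locus, J over the read
suffix after the V interval, and D (heavy chain) as the longest exact
common substring of the V–J gap, called `unassigned` below 5 consecutive
matching bases.  Ties break to the lexicographically smallest segment id
and are flagged.  A read whose best V alignment falls below 70% identity
over 50 nt is unannotatable: excluded from every statistic, counted in
the QC log.  Ungapped alignment is a deliberate scope decision — SHM is
overwhelmingly substitutional, and determinism plus testability beat
IgBlast feature parity for desk-scale and synthetic data.

Junction decomposition derives trims from the alignment intervals and
splits inter-segment bases greedily: maximal palindromic P (only at an
untrimmed end, up to 3 nt) first, remainder N.  P and N are reported
separately and pooled (`np1`/`np2`), since published junction summaries
do not always separate the two.

CDR3 spans from the first base of the V Cys104 codon (included) to the
first base of the J anchor codon (excluded); the J anchor plus following
Gly are verified as a motif and flagged, not enforced, because SHM can
mutate them.  The convention travels in the sidecar schema of every
written table.  A read is productive iff the two anchors are a multiple
of three apart and the aligned V..J translation is stop-free.  CDR1/2 on
the read come from nucleotide intervals annotated on the germline V
(explicit coordinates in the reference metadata; full IMGT unique
numbering is out of scope).

## Statistics

* Shannon-Weaver `H' = −Σ (n_i/N) ln(n_i/N)`, natural log only (no
  log2 option, to avoid silent unit drift).  The species unit defaults
  to the clonotype (joined CDR1-2-3); unique read sequences are an
  option, since the "species" of repertoire diversity is used both ways
  in practice.
* Usage frequencies include nonproductive reads by default (usage is a
  recombination property, not a selection property); CDR3 statistics are
  restricted to productive reads.  Duplicate weighting is a flag, both
  because copy number and unique-read conventions coexist in the field.
* Per-position SHM rate of a lineage at germline position p is
  `100 × mutated(p) / covering(p)`; the denominator counts only reads
  whose V alignment covers p, so truncated alignments do not deflate
  rates.  Normalisation maps p (0-based) to `round(100·(p+1)/L̄)` clipped
  to [1,100], with `L̄` the lineage's mean variable-region length; rates
  within a bin are averaged, empty bins stay 0 and inherit the preceding
  region label.  Aggregation across lineages is an unweighted mean by
  default (weighted by copies optional), so a single huge lineage cannot
  dominate the profile.
* Fold change normalises copies to per-10,000-read depth; lineages
  absent pre-immunization get a pseudocount of one normalised copy,
  always flagged.
* NJ dendrograms use normalised Levenshtein distance on CDR3 amino
  acids; tree construction is neighbour joining (scikit-bio), exact on
  additive matrices.  Leaf overlays are `min(copies, 50)` with the cap
  recorded.
* The divergence analysis excludes lineages with fewer than 100 reads
  in either sample (read-level counts), runs Welch's t test on per-read
  %diversity (`100 × mismatches / aligned V span`, junction excluded),
  classifies at raw P < 0.01 with exact mean ties assigned to the "not
  more diverged in sample 1" groups (conservative), and computes the
  odds score with a Haldane-Anscombe +0.5 correction on zero cells,
  flagged.  No multiple-testing correction by default — the
  classification is defined on raw P — with Benjamini-Hochberg available
  upstream of `classify_and_odds` if wanted.
* T20 humanness replaces the original hosted-database BLAST search with
  exhaustive global pairwise alignment (BLOSUM62-guided, identity
  counted as matches over alignment columns) against a user-supplied
  reference set; scores are comparable within a run.

## Numerical and design choices

* All coordinates are 0-based half-open, everywhere.
* Determinism: every stochastic stage consumes a named sub-seed spawned
  from the pipeline's global seed; reruns produce byte-identical TSVs.
  Alignment, grouping and naming ties all have documented deterministic
  tie-breaks (lexicographic ids, stable sorts).
* The lineage definition is V-D-J segment typing at gene level
  (allele-level and CDR3-length-augmented keys available); typing is the
  operational surrogate for "same rearrangement event" that repertoire
  pipelines can actually compute.
* Degenerate inputs: zero-variance Welch pairs return t=0, p=1 (equal
  means) or ±inf, p=0; single- and two-taxon NJ trees are emitted as
  degenerate Newick; empty tables raise informative errors rather than
  returning empty statistics.

## Problem sizes used in the checks

The bundled toy germline (8 IGHV / 5 IGHD / 4 IGHJ, 5 IGKV / 3 IGKJ,
one pseudogene per V locus) and these scales keep the full suite in the
tens of seconds while leaving the statistical assertions well-powered:
annotator equivalence at 1,000 reads per condition; parameter recovery
at 10,000 reads (3-SE binomial/distributional bands); hotspot recovery
over 100 lineages of 60 reads; odds-score null and alternative over 40
replicates of 200 lineages × 100 reads per arm; the demo pipeline at
2,000 reads.  Statistical checks at these sizes use ground-truth-derived
rearrangement tables (`truth_to_rearrangement`) where alignment adds
nothing to the property under test.

## Known limitations

The annotator handles substitutions only; indel-carrying reads
misalign or drop out.  Gene-level V accuracy degrades once SHM makes
same-subfamily segments mutually closer than the mutation load (not the
regime of the defaults).  The toy germline is synthetic: analyses of
real data need a real IMGT/OGRDB-derived reference supplied as
FASTA + metadata TSV, and humanness cutoffs transfer only as far as the
chosen reference set resembles a curated human database.
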