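# bcrkit

Analytics for B-cell receptor (BCR) immune repertoires from antibody
variable-region sequencing, aimed at studies that profile V(D)J gene
usage, junctional diversity, clonal expansion and somatic hypermutation
(SHM) — for example when characterising transgenic fully-human-antibody
animal platforms or germinal-centre responses.  Because deep-sequencing
repertoires are rarely redistributable, the package ships a synthetic
V(D)J repertoire generator with byte-exact ground truth, so every
analysis step can be validated against a repertoire whose true structure
is known.

## What it computes

**Simulation.** Reads are assembled as
`V(trimmed) + P + N1 + P + D(trimmed) + P + N2 + P + J(trimmed)` (heavy
chain; kappa reads have one V–J junction) with configurable segment
usage, geometric trimming, palindromic (P) and non-templated (N)
junction nucleotides, clonal lineage expansion and per-base SHM with a
CDR-biased hotspot multiplier.

**Annotation.** Germline V/D/J assignment by exact ungapped local
alignment, greedy P/N junction decomposition, CDR3 extraction between
the conserved Cys104 and the J Phe/Trp-118 anchor (Gly119 checked as a
flanking motif), productivity calling, and per-position V mutation
listing — into an AIRR-style rearrangement TSV.

**Repertoire statistics.** Segment usage frequencies, V(D)J combination
links with Circos-format export, CDR3 length/amino-acid composition,
N/P addition distributions, rarefaction, and the Shannon-Weaver index

```
H' = - Σ_{i=1..S} (n_i / N) ln(n_i / N)
```

over clonotype abundances `n_i` (`N` total reads, `S` species).

**Clonal analysis.** Clonotypes (joined CDR1-CDR2-CDR3 sequence), clone
lineages (shared V-D-J typing, named `CLH001…`/`CLL001…` by copy rank),
immunization fold change, SHM position profiles ("10 reads, 3 mutated at
one position → 30%") on a length-normalised 1..100 index, ≥2-mutation
burden, and neighbour-joining dendrograms of clonotypes with copy
overlays capped at 50.

**Divergence odds.** For lineages with ≥100 reads in both of two
samples, Welch's t test compares per-read %diversity from the germline
V; lineages fall into four groups at P < 0.01 (more/less diverged ×
significant/not) and the odds score `(|g1|/|g2|) / (|g3|/|g4|)`
summarises differential SHM accumulation.

**Humanness.** T20-style scoring: the mean percent identity of a query
variable region's top-20 matches in a user-supplied human reference set
(cutoffs 79 for FR+CDR, 86 for framework-only).

## Worked example

```python
import bcrkit
from bcrkit import clonal, stats

db = bcrkit.toy_germline()
config = bcrkit.SimulationConfig(n_reads=2000, n_lineages=200, shm_rate=0.01, seed=7)
reads = bcrkit.simulate_repertoire(db, config)
table = bcrkit.annotate_reads(reads.reads, db, "IGH").table

print(stats.cdr3_length_distribution(table).attrs["mean_length"])  # 14.85
d = stats.sample_diversity(table)
print(round(d.h_prime, 3), d.n_species)                            # 7.071 1642
print(clonal.group_lineages(table)[["name", "copy_count"]].head(2))
```

prints a mean CDR3 length of `14.85` amino acids (the junctional
arithmetic of the toy germline lands in the human 14–15 aa range), a
Shannon-Weaver `H' = 7.071` nats over `1642` clonotypes (close to the
`ln S = 7.404` maximum — clonal expansion pulls it slightly below
evenness), and the two largest clone lineages with their copy counts.
The scripts in `examples/` walk through each capability the same way
(simulation+annotation, statistics, clonal/SHM profiling, divergence
odds, humanness) and print a line on what each number means.

A thin CLI mirrors the stages:

```bash
bcrkit run --out-dir demo --seed 1          # end-to-end demo pipeline
bcrkit simulate --out-prefix sim            # or stage by stage
bcrkit annotate --reads sim.fasta --out rearr.tsv
bcrkit stats --rearr rearr.tsv --out-dir stats/
```

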