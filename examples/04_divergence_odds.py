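"""Two-sample divergence analysis with the lineage odds score.

Builds a paired design from one founder repertoire: sample 1 mutated at
1.5% per base (an immunized, affinity-maturing repertoire), sample 2 at
0.4% (unimmunized).  Lineages with fewer than 100 reads in either sample
are excluded; each remaining lineage gets a Welch t test on per-read
%diversity from the germline V, a four-group label at P < 0.01, and the
overall odds score (|g1|/|g2|)/(|g3|/|g4|).
"""

import bcrkit
from bcrkit import divergence

db = bcrkit.toy_germline()
base = dict(n_reads=1500, n_lineages=10, seed=21)
immunized = bcrkit.SimulationConfig(shm_rate=0.015, **base)
naive = bcrkit.SimulationConfig(shm_rate=0.004, **base)  # same founders: same seed

t1 = bcrkit.truth_to_rearrangement(bcrkit.simulate_repertoire(db, immunized).records, db, "IGH")
t2 = bcrkit.truth_to_rearrangement(bcrkit.simulate_repertoire(db, naive).records, db, "IGH")

result = bcrkit.divergence_analysis(t1, t2, min_copies=100, p_cutoff=0.01)
print(result.per_lineage[["lineage_key", "n1", "n2", "mean1", "mean2", "p", "group"]]
      .to_string(index=False))
print(f"\ngroup counts : {result.group_counts}")
print(f"odds score   : {result.odds_score:.2f}"
      + (" (continuity-corrected)" if result.continuity_corrected else ""))
# Odds far above 1 say that lineages significantly more diverged in
# sample 1 dominate: SHM accumulated differentially, as expected when
# sample 1 is the immunized repertoire.
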