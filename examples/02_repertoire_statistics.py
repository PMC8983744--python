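"""Descriptive repertoire statistics of one simulated sample.

Segment usage frequencies, V(D)J combination links, CDR3 length
distribution, junctional N lengths, productive fraction and the
Shannon-Weaver diversity index H' = -sum (n_i/N) ln(n_i/N).
"""

import bcrkit
from bcrkit import stats

db = bcrkit.toy_germline()
config = bcrkit.SimulationConfig(n_reads=2000, n_lineages=200, shm_rate=0.01, seed=7)
repertoire = bcrkit.simulate_repertoire(db, config)
table = bcrkit.annotate_reads(repertoire.reads, db, "IGH").table

usage = stats.usage_frequencies(table, "V")
print("V segment usage (%):")
print(usage.to_string(index=False))

cdr3 = stats.cdr3_length_distribution(table)
print(f"\nmean CDR3 length     : {cdr3.attrs['mean_length']} aa")

n_hist = stats.np_addition_distribution(table)
print(f"mean N1 insert       : {n_hist['n1'].attrs['mean']:.2f} nt")

diversity = stats.sample_diversity(table, unit="clonotype")
print(f"Shannon-Weaver H'    : {diversity.h_prime:.3f} nats "
      f"(max ln S = {diversity.h_max:.3f} over S = {diversity.n_species} clonotypes)")
print(f"productive fraction  : {stats.productive_fraction(table):.1f} %")
# H' close to ln S means clonotype abundances are nearly even; clonal
# expansion pulls H' below the maximum.
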