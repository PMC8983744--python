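"""T20-style humanness scoring of antibody variable regions.

Scores a query VH amino-acid sequence against a small reference set: the
T20 score is the mean percent identity of the 20 best global-alignment
matches.  Published cutoffs: above 79 for FR+CDR, above 86 for the
framework-only sequence.
"""

import bcrkit
from bcrkit.humanness import framework_sequence, score_queries, t20_score

query = "EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVS"

references = {
    f"human{i}": query[: 40 - i] + "AQKFQG" + query[46 - i :] for i in range(25)
}
references["distant"] = "DIQMTQSPSSLSASVGDRVTITC"

result = t20_score(query, references, mode="full", query_id="mAb-1")
print(f"T20 (FR+CDR)      : {result.t20_full:.1f}")
print(f"matches used      : {result.n_matches_used}")
print(f"passes cutoff 79  : {result.pass_full}")

table = score_queries({"mAb-1": query, "mAb-2": query[:30]}, references)
print("\n" + table.to_string(index=False))

fr = framework_sequence("AAABBBCCCDDDEEE", cdr1="BBB", cdr2="DDD", cdr3="")
print(f"\nframework-only of toy sequence: {fr}")
# Scores are comparable within one reference set; a score near 100 means
# the variable region is indistinguishable from the supplied human
# repertoire sequences.
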