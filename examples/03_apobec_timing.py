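"""APOBEC TpC* context tallies and mutation-timing enrichment.

Classifies every simulated SNV's strand-collapsed dinucleotide context
against the synthetic reference genome, then runs the two planned Fisher
comparisons: trunk vs germline (is the tumour lineage APOBEC-driven?) and
trunk vs private (did TpC* mutations accumulate early?).
"""

from clonetrace import (
    SimConfig, compare_tpc, partition_counts, simulate_patient,
    tally_contexts, trinucleotide_context,
)
from clonetrace.sharing import SharingClass

truth = simulate_patient(SimConfig(seed=5))
matrix = truth.truth_matrix()
partition = partition_counts(matrix)
contexts = [
    trinucleotide_context(truth.genome, m.chrom, m.pos, m.ref, m.alt)
    for m in matrix.markers
]
groups = {
    cls.value: [i for i, a in enumerate(partition.assignments) if a.sharing == cls]
    for cls in (SharingClass.ALL_SHARED, SharingClass.TUMOUR_SHARED,
                SharingClass.TUMOUR_PRIVATE)
}
print(tally_contexts(contexts, groups)[["group", "n", "TpC*", "tpc_fraction"]])

flags = [c.is_tpc if c.valid else None for c in contexts]
for name, g1, g2 in [
    ("trunk vs germline", "TUMOUR_SHARED", "ALL_SHARED"),
    ("trunk vs private (timing)", "TUMOUR_SHARED", "TUMOUR_PRIVATE"),
]:
    res = compare_tpc(flags, groups[g1], groups[g2], (g1, g2))
    print(f"{name}: fold={res.fold:.2f}, Fisher p={res.p_value:.3g}")
print(
    "(a ~6-fold trunk/germline enrichment with a vanishing p-value is the "
    "APOBEC signature; a fold >1 against private SNVs places it early in "
    "tumour development)"
)
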