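"""Build the BioNJ tree with bootstrap supports and call tumour clonality.

A clonal patient and a field-effect patient are simulated; for each, the
binary marker matrix (plus the all-zero reference pseudo-sample) is turned
into Euclidean distances, a BioNJ tree, and column-bootstrap supports.
Monophyly of the tumour samples distinguishes the two origins.
"""

from clonetrace import (
    SimConfig, add_reference_row, bootstrap_support, root_with_reference,
    simulate_patient, tumour_monophyly,
)

for label, cfg in [
    ("clonal", SimConfig(seed=11)),
    ("field-effect", SimConfig.field_default(seed=11)),
]:
    truth = simulate_patient(cfg)
    matrix = add_reference_row(truth.truth_matrix())
    tree = bootstrap_support(matrix, reps=1000, seed=11)
    mono = tumour_monophyly(tree, truth.roles)
    print(f"--- {label} patient ---")
    print(root_with_reference(tree).newick())
    print(
        f"tumours monophyletic: {mono.monophyletic}"
        + (f", clade support {mono.support:.0f} %" if mono.support is not None else "")
    )
    print(
        "(a 100 % supported tumour clade means every bootstrap replicate "
        "separates the tumours from normal + reference: a clonal origin)\n"
    )
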