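"""A custom symbolic query assembled in code.

This two-node query is the Z-step signature written out by hand: covalent
adjacency, conformational constraints per node, and a directional lp...pi
constraint (the first node owns the oxygen, the second the face).
"""

from zmotif import AnnotatedStructure, MotifQuery, run_query
from zmotif.fixtures import build_zhelix

query = MotifQuery(
    n_nodes=2,
    continuity=[(1, 2)],
    chi_constraints={1: "anti", 2: "syn"},
    pucker_constraints={1: "C2'-endo"},
    lppi_constraints={(1, 2): "sO4'3"},
)
hits = run_query(query, [AnnotatedStructure(build_zhelix())])
for h in hits:
    print(h.step_sequence, [f"{nt.base_type}{nt.seq_number}" for nt in h.nucleotides])
# Same three CpG steps the canned find_zsteps search reports.
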