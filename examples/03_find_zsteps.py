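"""Survey structures for Z-steps, with a negative control.

A Z-step needs four things at once: covalent adjacency, a 5' nucleotide in
anti with a C2'-endo sugar, a 3' nucleotide in syn, and the sO4'3 contact.
The A-form duplex satisfies none of the special ones and yields no hits.
"""

from zmotif import AnnotatedStructure, find_zsteps, survey_checks
from zmotif.fixtures import build_aform_duplex, build_zhelix

helix_hits = find_zsteps(AnnotatedStructure(build_zhelix()))
duplex_hits = find_zsteps(AnnotatedStructure(build_aform_duplex()))
print("Z-helix hits:", [h.step_sequence for h in helix_hits])
print("A-form duplex hits:", len(duplex_hits))
print("survey warnings:", survey_checks(helix_hits) or "none")
# Expected: three CpG hits from the Z-helix, zero from the duplex, and a
# clean survey (CpG is modal, no CpC step reported).
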