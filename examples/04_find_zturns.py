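"""Z-turn searches: loose versus strict constraint sets.

The loose UNNG query imposes only the sequence mask, chain continuity and
the tSW U*G loop pair; the strict query adds the nt4->nt5 sO4'3 contact
and anti constraints, the filter that separates genuine Z-turns from
look-alikes in low-resolution material.
"""

from zmotif import AnnotatedStructure, find_zturns
from zmotif.fixtures import build_gnna_zturn, build_uncg_zturn

turns = [AnnotatedStructure(build_uncg_zturn()),
         AnnotatedStructure(build_uncg_zturn(loop="UACG")),
         AnnotatedStructure(build_gnna_zturn())]

for template in ("UNNG", "GNNA"):
    for strictness in ("loose", "strict"):
        hits = find_zturns(turns, template, strictness)
        print(f"{template:5s} {strictness:6s}: "
              f"{[h.sequence for h in hits]}")
# The two UNNG loops match only the UNNG template and survive the strict
# filter (their Z-step is planted); the GAAA pentaloop-style turn matches
# only the GNNA template, which closes with a tSW G*A pair instead.
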