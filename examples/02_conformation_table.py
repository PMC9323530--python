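"""Per-nucleotide glycosidic and sugar-pucker annotation.

The UNCG Z-turn fixture shows the signature pattern: the loop's 3rd residue
is anti with a C2'-endo sugar and the loop G is syn.
"""

from zmotif import glycosidic, pucker
from zmotif.fixtures import build_uncg_zturn

for nt in build_uncg_zturn():
    g = glycosidic(nt)
    p = pucker(nt)
    print(f"{nt.base_type}{nt.seq_number}: chi = {g.chi:7.1f} deg ({g.cls:12s}) "
          f"P = {p.phase_P:6.1f} deg ({p.cls})")
# The chi column separates the syn loop guanine (~+60 deg) from the anti
# residues (~-160 deg); the pucker column shows the C2'-endo 5' sugar of
# the embedded CpG Z-step.
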