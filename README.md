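# zmotif

Lone-pair…π contact annotation and Z-step / Z-turn motif search in RNA 3D
structures.

## The problem

Z-steps are NpN dinucleotides isostructural to the CpG steps of left-handed
Z-DNA: the 5′ nucleotide is *anti* with a C2′-*endo* sugar, the 3′
nucleotide is *syn*, and — the defining feature — the O4′ oxygen of the 5′
ribose stacks on the 3′-face of the downstream nucleobase, a lone-pair…π
(oxygen…π) contact. The ubiquitous r(UNCG) tetraloop embeds exactly such a
CpG step and closes it with a *trans* Sugar/Watson–Crick (tSW) U•G pair;
loops with this architecture are Z-turns. These motifs are easy to miss
with conventional annotation because the χ torsions sit in borderline
regions and the decisive signal is the oxygen…face geometry.

`zmotif` is an offline library + CLI for people who want to find and
monitor these signatures in coordinate files — structural biologists
auditing deposited models, and simulators checking whether an MD ensemble
retains the native tetraloop signature.

## What it computes

For each nucleobase the package builds a reference frame: geometric center
(unweighted mean of the base heavy atoms), total-least-squares base plane,
and a signed normal whose positive side is the **3′-face** (the face toward
the 3′ chain direction in a regular helix). A backbone oxygen at signed
height z over the face is annotated:

* true contact `sO4′3` / `sOP15` / … when 2.0 Å < |z| ≤ 3.5 Å and its
  projection falls inside a base ring;
* near contact `nsO…` when 3.5 Å < |z| ≤ 3.6 Å over a ring, or |z| ≤ 3.5 Å
  just outside the ring but inside an ellipse expanded 0.3 Å beyond the
  ring corners.

On top of the contact layer: syn/anti χ classification, sugar pucker
(pseudorotation phase), hydrogen-bond detection, a reduced Leontis–Westhof
pair classifier (cWW, tSW/tWS and near variants), stacking faces
(s33/s35/s53/s55), and a symbolic constraint engine with canned searches
for Z-steps, Z_anti-steps, and UNNG / GNNA / CNNG Z-turns.

## Worked example

Everything is testable offline because the package ships a synthetic
geometry generator whose fixtures carry planted ground truth:

```python
from zmotif import AnnotatedStructure, find_zsteps, scan_structure
from zmotif.fixtures import build_zhelix, write_fixture
from zmotif.structure_io import load_structure

write_fixture(build_zhelix(), "zhelix.cif")      # (CG)3 with 3 planted Z-steps
meta, records = load_structure("zhelix.cif")

for ann in scan_structure(records, near=False):
    print(ann.oxygen_first_string, ann.base_nt.seq_number,
          "<-", ann.oxygen_nt.seq_number, round(ann.z, 2))

hits = find_zsteps(AnnotatedStructure(records, meta))
print([h.step_sequence for h in hits])
```

prints

```
sO4′3 2 <- 1 3.0
sO4′3 4 <- 3 3.0
sO4′3 6 <- 5 3.0
['CpG', 'CpG', 'CpG']
```

— three true O4′-on-3′-face contacts at z = 3.0 Å, one per CpG step, and
the Z-step survey finds exactly those three steps (the GpC junctions have
the wrong χ signature and are correctly skipped).

The same works from the shell on any local mmCIF/PDB file:

```sh
zmotif scan-lppi structure.cif               # contact table + breakdown
zmotif find-zsteps structure.cif             # Z-step survey
zmotif find-zturns --template UNNG --strictness strict structure.cif
zmotif find-zturns --template UNNG --set representative_set.txt --resolution-max 2.0
zmotif query --constraints my_query.txt structure.cif
```

where `representative_set.txt` holds one `PDBID|model|chain` per line with
the structure files alongside it, and a query file looks like

```
nodes=6
node2.base=U
node5.base=G
edge[1,2].next=1
edge[2,3].next=1
edge[3,4].next=1
edge[4,5].next=1
edge[5,6].next=1
edge[2,5].pair=n+tSW UG
edge[4,5].lppi=sO4′3
node4.chi=anti
```

See `examples/` for short narrative scripts, one per capability.

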