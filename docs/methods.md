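# Methods

## The contact model

A lone-pair…π (equivalently, oxygen…π) contact is the stacking of an RNA
backbone oxygen — OP1, OP2, O2′, O3′, O4′ or O5′ — over the face of a
nucleobase. Nucleobase oxygens (O2, O4, O6) and non-protonated nitrogens
are never treated as donors. With z the signed coordinate of the oxygen
along the base normal, the annotation rules are:

* **true contact** — 2.0 Å < |z| ≤ 3.5 Å and the in-plane projection of the
  oxygen falls strictly inside a base-ring polygon;
* **near, case 1** — 3.5 Å < |z| ≤ 3.6 Å, projection inside a ring;
* **near, case 2** — |z| ≤ 3.5 Å, projection outside every ring polygon but
  inside an ellipse fitted to the ring atoms and expanded so its boundary
  passes 0.3 Å radially beyond the most outlying ring corner.

The 2.0 Å lower bound excludes rare "in-plane" oxygen approaches; it is
part of the contact definition and is applied to all three cases (a
configuration flag limits it to the true band, since its application to
case-2 near contacts is a choice, not a forced consequence of the
definition). Exact boundary values (|z| = 3.5) count as true. Per ordered
(base, oxygen-owner) pair at most one oxygen is annotated: the smallest
|z| among in-ring candidates in the true band, else the smallest |z| in
the 3.5–3.6 band, else the expanded-ellipse candidate whose projection is
closest to the base center. Intra-nucleotide contacts (a residue's own
oxygen over its own base) are excluded by default and available as a
diagnostic flag.

Contacts render as directional strings: `sO4′3` (the owner's O4′ stacks on
the partner's 3′-face) and the mirror `s3O4′` (the base's 3′-face viewed
from the other side). A leading `n` marks a near contact; `n+` in a query
accepts both. `O` is generic over the six backbone oxygens and `OP` over
OP1/OP2; a constraint with no face digit matches either face. Both the
unicode prime and the ASCII apostrophe are accepted on input; output uses
the prime.

## Base frames and the 3′-face convention

The base center is the unweighted mean of the base heavy atoms, exocyclic
O/N included (a toggle restricts it to ring atoms for sensitivity checks).
The plane is the total-least-squares plane through the ring atoms
(smallest singular vector of the centred coordinates). The two faces of
the plane are named 3′ and 5′ by the direction the chain runs in a regular
helix: the positive normal points toward the 3′-face. The sign is fixed
per base type by the cross product of two intra-base vectors
(purines (N9→C8) × (N9→C4); pyrimidines (N1→C6) × (N1→C2)) and was
calibrated once against the package's own ideal A-form helix by requiring
that the normal of residue *i* point toward residue *i+1*; a test pins
this calibration. Because the sign is computed from atom positions alone
it is invariant under any rigid motion of the structure.

"Inside a ring" means strictly inside the polygon through the ring atoms;
the fitted ellipse (direct least-squares conic fit, Halir–Flusser) exists
only as the substrate for the expanded "near" boundary. Expansion scales
the fitted ellipse about its center so that the boundary passes exactly
0.3 Å beyond the most outlying ring corner; other corners are cleared by
slightly less, reflecting the fit residual (~0.01–0.03 Å on the standard
bases). When an oxygen projects inside both purine rings (possible only
near the fused bond) the ring with the nearer centroid wins.

## Conformation

χ is the torsion O4′–C1′–N9–C4 (purines) or O4′–C1′–N1–C2 (pyrimidines).
Default windows: syn = [0°, 90°], anti = [150°, 180°] ∪ (−180°, −90°],
otherwise intermediate. The windows are configurable because Z-step 3′
nucleotides often sit in borderline regions; the recommended alternative
is a stacking-face constraint (s53 for Z-steps, s55 for Z_anti-steps).
Note the conventional anti window is kept even though syn is sometimes
described as "about 60° instead of 120°" — 120° lies in neither
conventional regime and is classified intermediate here.

Sugar pucker uses the standard pseudorotation analysis of the five
endocyclic torsions (ν2 ∝ cos P), with class bands C3′-endo = [0°, 36°),
C4′-exo = [36°, 72°), C2′-endo = [144°, 180°), other elsewhere. A planar
ring (amplitude 0) is flagged degenerate.

The head-to-head/head-to-tail ribose orientation has no numeric definition
in the literature; the heuristic here (O4′→C1′ vectors antiparallel and
each O4′ on the facing side of the other ribose's mean plane) is
calibrated on the package's own Z-step fixtures and is advisory only — no
canned query uses it as a filter.

## Pairs and stacking

Hydrogen bonds are geometric: donor–acceptor heavy-atom distance ≤ 3.5 Å
(≤ 4.0 Å for "near" bonds), antecedent–donor–acceptor angle ≥ 110°, with
donor/acceptor tables per base and the 2′-OH acting on the sugar edge.
The Leontis–Westhof classifier is deliberately reduced: cWW and tSW/tWS
(with near variants) are the supported families — they are the ones the
Z-motif queries need — and anything else is reported with a provisional
marker. Edges are assigned by majority vote of the bonded atoms' edge
membership, using firm bonds only when any exist; ties yield no
annotation. cis/trans comes from the side of the C1′–C1′ axis on which
the two glycosidic bonds fall in the mean pair plane. True pairs require
inter-plane angles ≤ 35°; 35–55° (or only-near hydrogen bonds) makes the
pair near.

Base–base stacking: each base's center must project inside the other's
expanded-ellipse ring system with 2.0 Å < |z| ≤ 4.5 Å, in both directions
(one direction only ⇒ near). Faces read nt1-then-nt2: s53 means nt1's
5′-face meets nt2's 3′-face, the Z-step arrangement where the downstream
base is flipped syn. The 4.5 Å upper bound is plumbing, exposed in
`PairParameters`.

## Motif queries

A query is a small constraint graph: per-node base masks, χ and pucker
classes; per-edge "next" (covalent 5′→3′ adjacency: same chain and model,
successor author number, O3′–P ≤ 2.0 Å), pair family (with `n`/`n+`
widening, e.g. `n+tSW UG`), directional lp…π strings, and stacking faces.
Enumeration anchors on consecutive runs, then filters. Hits identical as
ordered nucleotide tuples are merged; overlapping shifted hits are kept.

Canned searches:

* **Z-step** — next + 5′-nt anti + 5′ sugar C2′-endo + 3′-nt syn +
  5′→3′ `sO4′3`; `stack_fallback` mode replaces the syn constraint with
  s53.
* **Z_anti-step** — next + `sO4′5` + 3′-nt anti (or s55).
* **Z-turns** — six nodes `n X N N Y n` with five next edges and the loop
  closing pair on nodes 2–5: tSW U•G (UNNG), tSW G•A (GNNA), tSW C•G
  (CNNG), cWW C=G for the CNNG Z_anti-turn. Strict mode adds the
  nt4→nt5 `sO4′3` (or `sO4′5` for the anti variant) and anti constraints
  on the loop. No stem (nodes 1–6) pairing is imposed by any template,
  which is what lets the GNNA template match bulged pentaloop geometries.

Surveys can be restricted by resolution using structure metadata;
structures without a recorded resolution are excluded from filtered
surveys with a logged count. Multi-model files annotate model 1 by
default. Modified nucleotides are skipped with a logged count; DNA
residues are parsed, flagged, and excluded from RNA motif searches unless
requested (the contact geometry itself is base-type agnostic).

Hit-set similarity is summarised as a matrix of superposition RMSDs over
node-matched base heavy atoms plus C1′ (for unlike sequences, a fixed
anchor subset: C1′, the glycosidic nitrogen and the χ-reference atom).
This is a plain RMSD, labelled as such in outputs — not a
geometric-discrepancy score.

## Synthetic fixtures

The generator builds nucleotides from an embedded planar base template per
base type (a single conformer, with ideal Watson–Crick complementarity
under a 180° flip) plus a ribose generated from the pseudorotation model.
The ribose ring is chain-built from the two driving endocyclic torsions
and solved numerically so the re-measured (P, amplitude) equals the
request to ~1e−10; the base is attached so measured χ equals the request
exactly. Substituent chirality matches β-D-ribofuranose (validated during
development against an independently embedded nucleotide).

Multi-nucleotide fixtures place rigid nucleotides by small deterministic
optimisations: the labelled geometry (the oxygen position over the base
face, the planted hydrogen-bond distances of a pair) is satisfied exactly
or to a stated tolerance; plumbing (backbone O3′–P adjacency ≤ 2.0 Å,
clash avoidance) is satisfied approximately. Defaults are the canonical
study conditions: Z-step = 5′-nt anti/C2′-endo, 3′-nt syn, O4′ at z = 3.0 Å
over the principal-ring centroid; the Z_anti-step uses a 3′ χ of −130°
(still anti) because covalent closure of the idealised backbone is
infeasible at −160°. The A-form duplex is generated by a screw fitted once
(axis on the pair dyad, slight inclination) so both strands are covalently
continuous; the (CG)ₙ Z-helix repeats a fitted dinucleotide screw whose
objective also keeps the GpC junctions free of incidental contacts. The
`stack_label` variants of the step builders use a closed-form placement
that additionally satisfies the mutual stacking criterion (s53/s55); they
are non-covalent two-base arrangements for stacking tests. Perturbation is
seeded isotropic Gaussian noise per atom.

What the fixtures do *not* emulate: crystallographic noise structure,
solvent, modified residues, realistic backbone rotamer distributions, or
electron-density-level ambiguity. Passing tests therefore demonstrate that
the geometric definitions are implemented correctly and consistently, not
that survey counts on real structures will match any particular published
survey; those depend on the deposited coordinates supplied by the user.

## Numerical choices

* Exact |z| = 3.5 Å is a true contact; polygon membership is strict
  (boundary = outside); candidate pruning radius 7 Å is provably non-lossy
  given |z| ≤ 3.6 Å and the < 3 Å in-plane extent of the ring systems.
* Ellipse fits use the numerically stable Halir–Flusser formulation; the
  degenerate (collinear) case raises.
* Optimisation-based fixture builders use fixed deterministic starts
  (Powell), so identical parameters and seed give identical coordinates.
* Acceptance-scale simulations use small corpora (a 6-nt Z-helix, 6-nt
  turn loops, a 6-bp duplex, ~60 nucleotides in total), chosen so the
  whole pipeline — file round trip, annotation, query — runs in minutes
  on one core.

## Known limitations

* The Leontis–Westhof surface is the reduced family set above; a full
  twelve-family classifier with established annotation-pipeline cutoffs is
  out of scope.
* Geometric (template/discrepancy) search, base–phosphate annotation,
  backbone suite names, Z_I/Z_II classification and solvent constraints
  are not implemented.
* Only the asymmetric unit is scanned; no symmetry-mate expansion.
* Representative-set surveys require the user to supply the structure
  files and the set list; published survey counts are only comparable
  when the same pinned list and files are used.
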