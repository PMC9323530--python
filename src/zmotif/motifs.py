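"""Symbolic constraint engine and canned Z-step / Z-turn searches.

A query is a small node-and-edge constraint graph over nucleotides: per
node a base mask and optional glycosidic-conformation requirement; per
ordered node pair optional constraints on covalent adjacency ("next"),
Leontis-Westhof pair family, lp...pi contact string, or stacking faces.
Enumeration anchors on the "next" edges: consecutive runs in one chain are
scanned first, then filtered by the remaining constraints, so exhaustive
search stays linear in structure size for chain-contiguous motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .base_frames import FrameError, compute_base_frame
from .conformation import ChiWindows, glycosidic, pucker
from .geometry import superposed_rmsd
from .lppi import LpPiAnnotation, LpPiParameters, parse_constraint, scan_structure
from .pairs import PairParameters, classify_lw, classify_stack
from .records import NucleotideRecord
from .reference import base_heavy_atoms

logger = logging.getLogger(__name__)


class QueryError(ValueError):
    """Malformed or unsatisfiable motif query."""


@dataclass
class MotifQuery:
    """Symbolic constraints over ``n_nodes`` nucleotides (1-based indices)."""

    n_nodes: int
    base_masks: dict = field(default_factory=dict)  # node -> set of bases; absent = N
    continuity: list = field(default_factory=list)  # (i, j): j is 5'->3' successor of i
    pair_constraints: dict = field(default_factory=dict)  # (i, j) -> "tSW UG" etc.
    lppi_constraints: dict = field(default_factory=dict)  # (i, j) -> "sO4'3" etc.
    chi_constraints: dict = field(default_factory=dict)  # node -> syn|anti
    pucker_constraints: dict = field(default_factory=dict)  # node -> C2'-endo etc.
    stack_constraints: dict = field(default_factory=dict)  # (i, j) -> "s53" etc.

    def validate(self) -> None:
        nodes = range(1, self.n_nodes + 1)
        for i in list(self.base_masks) + list(self.chi_constraints) + list(self.pucker_constraints):
            if i not in nodes:
                raise QueryError(f"constraint references node {i} of {self.n_nodes}")
        for i, j in (list(self.continuity) + list(self.pair_constraints)
                     + list(self.lppi_constraints) + list(self.stack_constraints)):
            if i not in nodes or j not in nodes:
                raise QueryError(f"edge ({i},{j}) references node outside 1..{self.n_nodes}")
        for text in self.lppi_constraints.values():
            parse_constraint(text)  # raises on malformed strings
        for text in self.pair_constraints.values():
            _parse_pair_constraint(text)


@dataclass
class MotifHit:
    structure_id: str
    nucleotides: tuple  # ordered NucleotideRecord per node
    report: dict = field(default_factory=dict)

    @property
    def sequence(self) -> str:
        return "".join(nt.base_type for nt in self.nucleotides)

    @property
    def keys(self):
        return tuple(nt.key for nt in self.nucleotides)

    @property
    def step_sequence(self) -> str:
        """NpN rendering for two-node hits."""
        return "p".join(nt.base_type for nt in self.nucleotides)


def _parse_pair_constraint(text: str):
    """Parse e.g. 'tSW UG', 'n+tSW UG', 'tSW ntSW UG', 'cWW'.

    Returns (allowed families with near prefix semantics, base pair mask or
    None).  Family tokens may carry an 'n' prefix (near only) or 'n+'
    (true and near).
    """
    tokens = text.replace("′", "'").split()
    if not tokens:
        raise QueryError("empty pair constraint")
    families = []  # (family, near_mode)
    mask = None
    for tok in tokens:
        if len(tok) == 2 and all(c in "ACGUN" for c in tok):
            mask = tok
            continue
        near_mode = "true"
        fam = tok
        if fam.startswith("n+"):
            near_mode, fam = "both", fam[2:]
        elif fam.startswith("n") and len(fam) == 4:
            near_mode, fam = "near", fam[1:]
        if len(fam) != 3 or fam[0] not in "ct" or any(c not in "WHS" for c in fam[1:]):
            raise QueryError(f"bad pair family {tok!r} in {text!r}")
        families.append((fam, near_mode))
    if not families:
        raise QueryError(f"no pair family in {text!r}")
    return families, mask


def _pair_matches(ann, families, mask, b1, b2) -> bool:
    if ann is None:
        return False
    if mask is not None:
        for m, b in zip(mask, (b1, b2)):
            if m != "N" and m != b:
                return False
    for fam, near_mode in families:
        if ann.family != fam:
            continue
        if near_mode == "true" and not ann.near:
            return True
        if near_mode == "near" and ann.near:
            return True
        if near_mode == "both":
            return True
    return False


class AnnotatedStructure:
    """A structure with lazily computed annotations shared across queries."""

    def __init__(self, records, meta=None,
                 lppi_params: LpPiParameters | None = None,
                 pair_params: PairParameters | None = None,
                 chi_windows: ChiWindows | None = None,
                 include_dna: bool = False):
        records = [r for r in records if include_dna or not r.is_dna]
        self.records = sorted(records, key=lambda r: r.key)
        self.meta = meta
        self.lppi_params = lppi_params or LpPiParameters()
        self.pair_params = pair_params or PairParameters()
        self.chi_windows = chi_windows or ChiWindows()
        self.by_key = {r.key: r for r in self.records}
        self.frames = {}
        for rec in self.records:
            if not rec.annotatable:
                continue
            try:
                self.frames[rec.key] = compute_base_frame(
                    rec, ellipse_expansion=self.lppi_params.ellipse_expansion
                )
            except FrameError:
                continue
        self._lppi = None
        self._chi = {}
        self._pucker = {}
        self._pairs = {}
        self._stacks = {}
        self._successors = None

    @property
    def structure_id(self) -> str:
        return self.records[0].structure_id if self.records else ""

    # -- annotations -------------------------------------------------------

    def lppi(self) -> list[LpPiAnnotation]:
        if self._lppi is None:
            self._lppi = scan_structure(self.records, self.lppi_params,
                                        near=True, frames=self.frames)
        return self._lppi

    def lppi_for(self, oxygen_key, base_key) -> LpPiAnnotation | None:
        for ann in self.lppi():
            if ann.oxygen_nt == oxygen_key and ann.base_nt == base_key:
                return ann
        return None

    def chi(self, key):
        if key not in self._chi:
            try:
                self._chi[key] = glycosidic(self.by_key[key], self.chi_windows)
            except ValueError:
                self._chi[key] = None
        return self._chi[key]

    def sugar(self, key):
        if key not in self._pucker:
            try:
                self._pucker[key] = pucker(self.by_key[key])
            except ValueError:
                self._pucker[key] = None
        return self._pucker[key]

    def pair(self, k1, k2):
        if (k1, k2) not in self._pairs:
            self._pairs[(k1, k2)] = classify_lw(
                self.by_key[k1], self.by_key[k2], self.pair_params, self.frames
            )
        return self._pairs[(k1, k2)]

    def stack(self, k1, k2):
        if (k1, k2) not in self._stacks:
            self._stacks[(k1, k2)] = classify_stack(
                self.by_key[k1], self.by_key[k2], self.pair_params, self.frames
            )
        return self._stacks[(k1, k2)]

    def successors(self) -> dict:
        """key -> key of the covalent 5'->3' successor (same chain and model,
        next author number, O3'-P distance <= 2.0 A)."""
        if self._successors is None:
            self._successors = {}
            by_chain = {}
            for rec in self.records:
                by_chain.setdefault((rec.model, rec.chain), []).append(rec)
            for group in by_chain.values():
                group.sort(key=lambda r: (r.seq_number, r.insertion_code))
                for a, b in zip(group, group[1:]):
                    if "O3'" not in a.atoms or "P" not in b.atoms:
                        continue
                    d = float(np.linalg.norm(a.atoms["O3'"] - b.atoms["P"]))
                    if d <= 2.0:
                        self._successors[a.key] = b.key
        return self._successors

    def consecutive_runs(self, length: int):
        """All runs of ``length`` covalently consecutive nucleotides."""
        succ = self.successors()
        runs = []
        for rec in self.records:
            run = [rec.key]
            while len(run) < length and run[-1] in succ:
                run.append(succ[run[-1]])
            if len(run) == length:
                runs.append(tuple(run))
        return runs


def run_query(query: MotifQuery, structures) -> list[MotifHit]:
    """Evaluate a symbolic query over annotated structures.

    ``structures`` is an iterable of AnnotatedStructure (or record lists,
    which are wrapped on the fly).  Hits are deduplicated on their ordered
    nucleotide key tuple and returned in deterministic order.
    """
    query.validate()
    out = []
    for st in structures:
        if not isinstance(st, AnnotatedStructure):
            st = AnnotatedStructure(st)
        # duplicate node mappings within one structure are emitted once;
        # distinct structures are never merged, even under equal ids
        seen = set()
        for h in sorted(_query_structure(query, st), key=lambda h: h.keys):
            if h.keys not in seen:
                seen.add(h.keys)
                out.append(h)
    return out


def _candidate_tuples(query: MotifQuery, st: AnnotatedStructure):
    nodes = list(range(1, query.n_nodes + 1))
    chain_edges = set(query.continuity)
    if set(chain_edges) >= {(i, i + 1) for i in nodes[:-1]}:
        # fully chained motif: enumerate consecutive runs
        for run in st.consecutive_runs(query.n_nodes):
            yield run
        return
    # partial continuity: enumerate runs for each chained block and join the
    # rest exhaustively (adequate for the small motifs handled here)
    succ = st.successors()
    keys = [r.key for r in st.records]

    def extend(assign, node):
        if node > query.n_nodes:
            yield tuple(assign[i] for i in nodes)
            return
        prev_edge = (node - 1, node)
        if prev_edge in chain_edges:
            prev = assign[node - 1]
            nxt = succ.get(prev)
            if nxt is None:
                return
            assign[node] = nxt
            yield from extend(assign, node + 1)
            del assign[node]
        else:
            used = set(assign.values())
            for k in keys:
                if k in used:
                    continue
                assign[node] = k
                yield from extend(assign, node + 1)
                del assign[node]

    yield from extend({}, 1)


def _query_structure(query: MotifQuery, st: AnnotatedStructure):
    hits = []
    for keys in _candidate_tuples(query, st):
        if _check_tuple(query, st, keys):
            nts = tuple(st.by_key[k] for k in keys)
            hits.append(MotifHit(structure_id=st.structure_id, nucleotides=nts))
    return hits


def _check_tuple(query: MotifQuery, st: AnnotatedStructure, keys) -> bool:
    for node, mask in query.base_masks.items():
        base = st.by_key[keys[node - 1]].base_type
        allowed = set(mask) if not isinstance(mask, (set, frozenset)) else mask
        if "N" not in allowed and base not in allowed:
            return False
    for node, want in query.chi_constraints.items():
        if want in (None, "any"):
            continue
        ann = st.chi(keys[node - 1])
        if ann is None or ann.cls != want:
            return False
    for node, want in query.pucker_constraints.items():
        ann = st.sugar(keys[node - 1])
        if ann is None or ann.cls != want:
            return False
    for (i, j), text in query.pair_constraints.items():
        families, mask = _parse_pair_constraint(text)
        ann = st.pair(keys[i - 1], keys[j - 1])
        if not _pair_matches(ann, families, mask,
                             st.by_key[keys[i - 1]].base_type,
                             st.by_key[keys[j - 1]].base_type):
            return False
    for (i, j), text in query.lppi_constraints.items():
        c = parse_constraint(text)
        if c.base_first:
            base_key, oxy_key = keys[i - 1], keys[j - 1]
        else:
            oxy_key, base_key = keys[i - 1], keys[j - 1]
        ann = st.lppi_for(oxy_key, base_key)
        if ann is None or not c.matches(ann):
            return False
    for (i, j), faces in query.stack_constraints.items():
        ann = st.stack(keys[i - 1], keys[j - 1])
        if ann is None or ann.faces != faces or ann.near:
            return False
    return True


# ---------------------------------------------------------------------------
# canned searches
# ---------------------------------------------------------------------------


def find_zsteps(structure, mode: str = "strict") -> list[MotifHit]:
    """Survey a structure for Z-steps.

    ``strict``: two consecutive nucleotides with the 5' base anti, the 5'
    sugar C2'-endo, the 3' base syn, and an sO4'3 contact from the 5'
    ribose onto the 3' base.  ``stack_fallback`` replaces the syn
    constraint with an s53 stacking constraint, the recommended filter
    when chi is borderline.
    """
    if mode not in ("strict", "stack_fallback"):
        raise QueryError(f"unknown Z-step mode {mode!r}")
    q = MotifQuery(
        n_nodes=2,
        continuity=[(1, 2)],
        chi_constraints={1: "anti"},
        pucker_constraints={1: "C2'-endo"},
        lppi_constraints={(1, 2): "sO4'3"},
    )
    if mode == "strict":
        q.chi_constraints[2] = "syn"
    else:
        q.stack_constraints[(1, 2)] = "s53"
    return run_query(q, [structure])


def find_zanti_steps(structure, mode: str = "strict") -> list[MotifHit]:
    """Z_anti-steps: consecutive pair, sO4'5 contact, 3' base anti
    (``stack_fallback`` substitutes an s55 stacking constraint)."""
    if mode not in ("strict", "stack_fallback"):
        raise QueryError(f"unknown Z_anti-step mode {mode!r}")
    q = MotifQuery(
        n_nodes=2,
        continuity=[(1, 2)],
        lppi_constraints={(1, 2): "sO4'5"},
    )
    if mode == "strict":
        q.chi_constraints[2] = "anti"
    else:
        q.stack_constraints[(1, 2)] = "s55"
    return run_query(q, [structure])


#: canned 6-node Z-turn templates: base masks for nodes 1..6 and the loop
#: pair constraint on nodes (2, 5)
_ZTURN_TEMPLATES = {
    "UNNG": ({2: "U", 5: "G"}, "tSW UG"),
    "GNNA": ({2: "G", 5: "A"}, "tSW GA"),
    "CNNG": ({2: "C", 5: "G"}, "tSW CG"),
    "zanti_CNNG": ({2: "C", 5: "G"}, "cWW CG"),
}


def zturn_query(template: str = "UNNG", strictness: str = "loose",
                near_pairs: bool = False) -> MotifQuery:
    """Build the 6-node Z-turn query for a named template.

    Loose: r(nXNNYn) base mask, five "next" edges, and the loop closing
    pair (tSW for the Z-turns, cWW for the CNNG Z_anti-turn).  Strict adds
    the nt4-nt5 lp...pi constraint (sO4'3, or sO4'5 for the anti variant)
    and anti on nt3/nt4 (for the anti variant, anti on the loop G).
    ``near_pairs`` widens the pair constraint to true + near families.
    """
    if template not in _ZTURN_TEMPLATES:
        raise QueryError(f"unknown Z-turn template {template!r}")
    if strictness not in ("loose", "strict"):
        raise QueryError(f"unknown strictness {strictness!r}")
    masks, pair = _ZTURN_TEMPLATES[template]
    if near_pairs:
        fam, bases = pair.split()
        pair = f"n+{fam} {bases}"
    q = MotifQuery(
        n_nodes=6,
        base_masks=dict(masks),
        continuity=[(i, i + 1) for i in range(1, 6)],
        pair_constraints={(2, 5): pair},
    )
    if strictness == "strict":
        if template == "zanti_CNNG":
            q.lppi_constraints[(4, 5)] = "sO4'5"
            q.chi_constraints[5] = "anti"
        else:
            q.lppi_constraints[(4, 5)] = "sO4'3"
            q.chi_constraints[3] = "anti"
            q.chi_constraints[4] = "anti"
    return q


def find_zturns(structures, template: str = "UNNG", strictness: str = "loose",
                near_pairs: bool = False) -> list[MotifHit]:
    """Run a canned Z-turn (or Z_anti-turn) search over structures."""
    return run_query(zturn_query(template, strictness, near_pairs), structures)


def mutual_similarity_matrix(hits) -> np.ndarray:
    """Pairwise structural similarity of motif hits, as an RMSD matrix (A).

    Entry (i, j) is the RMSD over node-matched base heavy atoms plus C1'
    after optimal rigid superposition.  This is a plain superposition RMSD,
    not a geometric-discrepancy score; it is symmetric with a zero
    diagonal.
    """
    hits = list(hits)
    if len(hits) < 2:
        raise ValueError("need at least two hits")
    n_nodes = {len(h.nucleotides) for h in hits}
    if len(n_nodes) != 1:
        raise ValueError("hits have mismatched node counts")

    def full_coords(hit):
        pts = []
        for nt in hit.nucleotides:
            names = ["C1'"] + [a for a in base_heavy_atoms(nt.base_type) if a in nt.atoms]
            pts.extend(nt.atoms[a] for a in names)
        return np.array(pts)

    def anchor_coords(hit):
        # fixed-size representation comparable across unlike sequences:
        # C1', the glycosidic nitrogen and the chi-reference ring atom
        from .reference import CHI_REFERENCE, GLYCOSIDIC_N

        pts = []
        for nt in hit.nucleotides:
            for a in ("C1'", GLYCOSIDIC_N[nt.base_type], CHI_REFERENCE[nt.base_type]):
                pts.append(nt.atoms[a])
        return np.array(pts)

    same_seq = len({h.sequence for h in hits}) == 1
    mats = [full_coords(h) if same_seq else anchor_coords(h) for h in hits]
    n = len(hits)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = superposed_rmsd(mats[i], mats[j])
    return out


def survey_checks(zstep_hits) -> list[str]:
    """Warning-level consistency checks on a Z-step survey.

    CpG is expected to be the modal Z-step sequence in any realistic
    corpus, and CpC Z-steps have never been reported; deviations are
    returned as warning strings, not errors.
    """
    warnings = []
    seqs = [h.step_sequence for h in zstep_hits]
    if seqs:
        counts = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        modal = max(counts, key=lambda k: (counts[k], k))
        if modal != "CpG":
            warnings.append(f"modal Z-step sequence is {modal}, expected CpG")
        if counts.get("CpC"):
            warnings.append(f"found {counts['CpC']} CpC Z-steps; none have been reported")
    return warnings
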