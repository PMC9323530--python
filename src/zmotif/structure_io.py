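"""Reading mmCIF/PDB files into nucleotide records.

Parsing is delegated to gemmi; this module only decides which residues and
which alternate locations enter the annotation pipeline.  Waters, ions,
amino acids and modified nucleotides are skipped (the latter with a logged
count).  When an atom is present in several alternate locations, the
lexicographically first altloc is stored together with its occupancy, so
that the occupancy-based filtering policy can be applied downstream.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np

from .records import NucleotideRecord, StructureMeta
from .reference import ALL_RING_ATOMS, BACKBONE_OXYGENS, DNA_EQUIVALENT, STANDARD_BASES, normalize_atom_name

logger = logging.getLogger(__name__)

_SKIP_RESIDUES = {"HOH", "DOD", "MG", "K", "NA", "CL", "ZN", "MN", "CA", "SO4", "PO4"}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be read."""


def load_structure(
    path,
    fmt: str = "auto",
    models: str | int = 1,
    include_dna: bool = True,
):
    """Parse an mmCIF or PDB file into (StructureMeta, [NucleotideRecord]).

    Parameters
    ----------
    path
        Coordinate file (mmCIF or PDB; ``fmt`` may force a dialect).
    models
        ``1`` (default) reads the first model only, ``"all"`` reads every
        model of an ensemble, an integer selects that model number.
    include_dna
        Parse DA/DC/DG/DT residues too (flagged ``is_dna``).

    Returns one record per RNA (and optionally DNA) residue per selected
    model.  Non-nucleotide residues are skipped; modified nucleotides are
    skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from exc

    st.setup_entities()
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    meta = StructureMeta(
        structure_id=st.name or path.stem.upper(),
        resolution=resolution,
        method=dict(st.info.items()).get("_exptl.method", ""),
        n_models=len(st),
    )

    records: list[NucleotideRecord] = []
    n_modified = 0
    for i_model, model in enumerate(st, start=1):
        if models != "all" and i_model != int(models):
            continue
        for chain in model:
            for res in chain:
                name = res.name.strip()
                base = None
                is_dna = False
                if name in STANDARD_BASES:
                    base = name
                elif name in DNA_EQUIVALENT:
                    if not include_dna:
                        continue
                    base, is_dna = DNA_EQUIVALENT[name], True
                elif name in _SKIP_RESIDUES or res.is_water():
                    continue
                elif _looks_like_nucleotide(res):
                    n_modified += 1
                    continue
                else:
                    continue
                rec = _residue_to_record(meta.structure_id, i_model, chain.name, res, base, is_dna)
                if rec.atoms:
                    records.append(rec)

    if n_modified:
        logger.info("%s: skipped %d modified nucleotides", meta.structure_id, n_modified)
    if not records:
        logger.warning("%s: no RNA residues found", meta.structure_id)
    return meta, records


def _looks_like_nucleotide(res) -> bool:
    names = {normalize_atom_name(a.name) for a in res}
    return "C1'" in names and ("N9" in names or "N1" in names) and "P" in names


def _residue_to_record(structure_id, model, chain, res, base, is_dna) -> NucleotideRecord:
    rec = NucleotideRecord(
        structure_id=structure_id,
        model=model,
        chain=chain,
        seq_number=res.seqid.num,
        insertion_code=(res.seqid.icode or "").strip(),
        base_type=base,
        is_dna=is_dna,
    )
    for atom in res:
        name = normalize_atom_name(atom.name)
        alt = atom.altloc or ""
        if name in rec.atoms and alt >= rec.altloc.get(name, ""):
            continue  # keep the lexicographically first altloc
        rec.atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        rec.occupancy[name] = float(atom.occ)
        rec.altloc[name] = alt
    return rec


def filter_altlocs(records, policy: str = "exclude_partial"):
    """Apply the partial-occupancy policy for annotation.

    ``exclude_partial`` (default) drops any nucleotide whose base-ring or
    backbone-oxygen atoms carry occupancy < 1.0, so that alternate
    conformations never enter the contact statistics.  ``keep_first``
    retains every nucleotide using the lexicographically first altloc
    already stored at parse time (with a logged note).
    """
    if policy == "keep_first":
        n_alt = sum(1 for r in records if any(a for a in r.altloc.values()))
        if n_alt:
            logger.info("keep_first altloc policy: %d nucleotides carry altlocs", n_alt)
        return list(records)
    if policy != "exclude_partial":
        raise ValueError(f"unknown altloc policy {policy!r}")
    kept = []
    for rec in records:
        checked = list(ALL_RING_ATOMS[rec.base_type]) + list(BACKBONE_OXYGENS)
        partial = any(rec.occupancy.get(n, 1.0) < 1.0 for n in checked if n in rec.atoms)
        if not partial:
            kept.append(rec)
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("altloc filter dropped %d nucleotides with partial occupancy", n_dropped)
    return kept


def read_set_list(path):
    """Read a representative-set list file: one ``PDBID|model|chain`` per line.

    Returns a list of (pdb_id, model, chain) triples.  Blank lines and
    ``#`` comments are ignored; model defaults to 1 and chain to all chains
    when the fields are omitted.
    """
    entries = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = (line.split("|") + ["1", ""])[:3]
        pdb_id = parts[0].strip().upper()
        if not pdb_id:
            raise ValueError(f"{path}:{i}: empty structure id")
        model = int(parts[1]) if parts[1].strip() else 1
        entries.append((pdb_id, model, parts[2].strip()))
    return entries
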