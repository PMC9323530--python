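import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from zmotif import AnnotatedStructure
from zmotif.fixtures import (
    build_aform_duplex,
    build_cnng_zanti_turn,
    build_gnna_zturn,
    build_nucleotide,
    build_pair,
    build_uncg_zturn,
    build_zanti_step,
    build_zhelix,
    build_zstep,
)
from zmotif.records import NucleotideRecord
from zmotif.reference import BASE_TEMPLATES


def make_base_record(base: str, seq: int = 1, chain: str = "A") -> NucleotideRecord:
    """Bare planar base (template coordinates) with C1', no ribose."""
    return NucleotideRecord(
        structure_id="TEST", model=1, chain=chain, seq_number=seq,
        insertion_code="", base_type=base,
        atoms={k: v.copy() for k, v in BASE_TEMPLATES[base].items()},
    )


@pytest.fixture(scope="session")
def zstep():
    return build_zstep()


@pytest.fixture(scope="session")
def zanti_step():
    return build_zanti_step()


@pytest.fixture(scope="session")
def uncg_zturn():
    return build_uncg_zturn()


@pytest.fixture(scope="session")
def gnna_zturn():
    return build_gnna_zturn()


@pytest.fixture(scope="session")
def cnng_zanti_turn():
    return build_cnng_zanti_turn()


@pytest.fixture(scope="session")
def aform_duplex():
    return build_aform_duplex()


@pytest.fixture(scope="session")
def zhelix():
    return build_zhelix()


@pytest.fixture(scope="session")
def tsw_ug_pair():
    return build_pair("tSW", ("U", "G"))


@pytest.fixture(scope="session")
def cww_gc_pair():
    return build_pair("cWW", ("G", "C"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240365)


def random_rigid_motion(rng):
    """Uniform-ish random rotation (QR of a Gaussian matrix) + translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return Q, t


def moved(rec: NucleotideRecord, R, t) -> NucleotideRecord:
    out = NucleotideRecord(
        structure_id=rec.structure_id, model=rec.model, chain=rec.chain,
        seq_number=rec.seq_number, insertion_code=rec.insertion_code,
        base_type=rec.base_type,
        atoms={k: R @ v + t for k, v in rec.atoms.items()},
        occupancy=dict(rec.occupancy), altloc=dict(rec.altloc),
    )
    return out


def annotated(records) -> AnnotatedStructure:
    return AnnotatedStructure(records)
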