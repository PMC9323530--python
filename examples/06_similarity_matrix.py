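"""Mutual structural similarity of motif hits.

After a search, the pairwise superposition RMSD matrix is the quickest way
to spot outliers: a hit whose row is uniformly large deviates from the
rest of the ensemble and deserves individual inspection.
"""

import numpy as np

from zmotif import AnnotatedStructure, find_zturns, mutual_similarity_matrix
from zmotif.fixtures import build_uncg_zturn, perturb

structures = [AnnotatedStructure(perturb(build_uncg_zturn(), 0.08, seed=s))
              for s in range(4)]
hits = find_zturns(structures, "UNNG", "loose")
m = mutual_similarity_matrix(hits)
print(np.round(m, 2))
# Symmetric, zero diagonal; off-diagonal entries around twice the 0.08 A
# per-atom noise, since each hit carries its own independent perturbation.
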