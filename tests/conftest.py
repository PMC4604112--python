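import logging

import numpy as np
import pytest

from chemomine.seqcore import NucSequence, ProtSequence
from chemomine.synthetic import make_gpcr_family, _back_translate

logging.getLogger("chemomine").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def gpcr_family():
    """One simulated 7-TM family: (references, profile, ancestor protein)."""
    return make_gpcr_family(n_refs=6, length_aa=310, divergence=0.10, seed=11)


@pytest.fixture(scope="session")
def ancestor_cds(gpcr_family):
    """A clean full ORF (ATG ... stop) encoding the family ancestor."""
    _, _, ancestor = gpcr_family
    rng = np.random.default_rng(5)
    return _back_translate(rng, ancestor) + "TGA"


def embed_gene(cds: str, left: int = 2000, right: int = 2000, seed: int = 0,
               scaffold_id: str = "scf1") -> NucSequence:
    """Plant a coding sequence in uniform random background."""
    rng = np.random.default_rng(seed)
    flank = lambda n: "".join("ACGT"[i] for i in rng.integers(4, size=n))
    return NucSequence(id=scaffold_id, residues=flank(left) + cds + flank(right))


@pytest.fixture(scope="session")
def planted_scaffold(ancestor_cds):
    """(scaffold, cds_start, cds_end) with the ancestor ORF at a known spot."""
    scaf = embed_gene(ancestor_cds, seed=3)
    return scaf, 2000, 2000 + len(ancestor_cds)
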