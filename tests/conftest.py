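import numpy as np
import pytest

from toxassay.arena import ArenaSpec
from toxassay.metabarcoding import DBEntry, ReferenceDB


@pytest.fixture
def arena() -> ArenaSpec:
    """Default shrimp-assay vessel: 275 x 80 mm, 3 x 5 grid, anemone centred."""
    return ArenaSpec()


def random_reference_db(n_taxa: int, length: int = 600, seed: int = 0) -> ReferenceDB:
    """Synthetic reference database of random sequences with lineages."""
    rng = np.random.default_rng(seed)
    phyla = ["Arthropoda", "Annelida", "Mollusca", "Chordata"]
    entries = []
    for i in range(n_taxa):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        phylum = phyla[i % len(phyla)]
        entries.append(DBEntry(f"taxon_{i:02d}", f"k__Animalia;p__{phylum}", seq))
    return ReferenceDB(entries)


@pytest.fixture
def toy_db() -> ReferenceDB:
    return random_reference_db(5, seed=11)
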