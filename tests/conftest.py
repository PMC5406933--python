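import numpy as np
import pytest
from hypothesis import settings

from sialomine import Catalogue, Contig, LibrarySpec

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_catalogue(counts_by_contig, lib_conditions, **contig_kwargs):
    """Build a small in-memory catalogue.

    counts_by_contig: {contig_id: {lib_id: count}}
    lib_conditions: {lib_id: host_condition}
    contig_kwargs: {contig_id: dict of Contig field overrides}
    """
    libs = {
        lid: LibrarySpec(library_id=lid, host_condition=cond)
        for lid, cond in lib_conditions.items()
    }
    contigs = {
        cid: Contig(contig_id=cid, counts=dict(c), **contig_kwargs.get(cid, {}))
        for cid, c in counts_by_contig.items()
    }
    return Catalogue(libraries=libs, contigs=contigs)


@pytest.fixture
def toy_catalogue():
    """Two libraries (one per host condition), four contigs."""
    return make_catalogue(
        {
            "c1": {"LibR": 30, "LibS": 30},
            "c2": {"LibR": 5, "LibS": 27},
            "c3": {"LibR": 12, "LibS": 3},
            "c4": {"LibR": 1, "LibS": 2},
        },
        {"LibR": "resistant", "LibS": "susceptible"},
        c1={"description": "beta actin"},
        c2={
            "description": "Kunitz domain proteinase inhibitor",
            "signal_peptide": True,
            "category": "secreted",
            "family": "Kunitz domain",
        },
        c3={"description": "hypothetical protein"},
        c4={"description": "salivary mucin", "signal_peptide": True},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
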