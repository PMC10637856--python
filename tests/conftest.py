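from __future__ import annotations

import pytest

from openmoa import InteractionRecord, build_reference_network
from openmoa.ingest import DRUG_TARGET, PPI, REGULATORY


def make_network(drug=(), ppi=(), regulatory=()):
    """Build a network from bare (source, target) pairs per edge type."""
    drug_recs = [InteractionRecord(a, b, DRUG_TARGET) for a, b in drug]
    ppi_recs = [
        InteractionRecord(
            a,
            b,
            PPI,
            combined_score=900,
            experimental_score=100,
            experimental_transferred_score=0,
        )
        for a, b in ppi
    ]
    reg_recs = [InteractionRecord(a, b, REGULATORY) for a, b in regulatory]
    return build_reference_network(drug_recs, ppi_recs, reg_recs)


@pytest.fixture
def chain_network():
    """DRUG1 -> A, A-B and B-T PPIs, TF T regulating G.

    The unique constrained shortest path from A to G is A->B->T->G.
    """
    return make_network(
        drug=[("DRUG1", "A")],
        ppi=[("A", "B"), ("B", "T")],
        regulatory=[("T", "G")],
    )


@pytest.fixture
def fork_network():
    """S reaches G through two TFs: S-X-.. and S-Y-.., X->G and Y->G."""
    return make_network(
        ppi=[("S", "X"), ("S", "Y")],
        regulatory=[("X", "G"), ("Y", "G")],
    )
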