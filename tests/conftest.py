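"""Shared fixtures: idealized pairs and the miniature decoding-center system.

Fixture construction runs a deterministic optimizer, so the expensive ones
are session-scoped and treated as read-only by tests.
"""

import pytest

from ribocar import synthetic as syn


@pytest.fixture(scope="session")
def gc_pair():
    """Ideal Watson-Crick G:C pair (chains A/B, residue 1 each)."""
    return syn.make_pair(syn.PairGeometrySpec("wc", "G", "C"))


@pytest.fixture(scope="session")
def ac_pair():
    """Ideal trans Watson-Crick/Hoogsteen ('reverse Hoogsteen') A:C pair."""
    return syn.make_pair(syn.PairGeometrySpec("trans_wc_hoogsteen", "A", "C"))


@pytest.fixture(scope="session")
def au_pair():
    return syn.make_pair(syn.PairGeometrySpec("wc", "A", "U"))


@pytest.fixture(scope="session")
def car_fixture():
    """Miniature CAR decoding-center neighborhood with +1 codon GCU."""
    return syn.make_car_fixture("GCU")


@pytest.fixture(scope="session")
def car_fixture_ggu():
    """Same fixture with the purine substitution G at +1 position 2."""
    return syn.make_car_fixture("GGU")


@pytest.fixture(scope="session")
def strand10():
    """Ten stacked nucleotides on one chain — the generic helix fixture."""
    return syn.make_mrna_strand("AUGCCUGCUA")
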