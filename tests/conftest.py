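"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import strategies as st

from paircraft import PairingGraph, SecondaryStructure, SegmentSpec


@st.composite
def pair_sets(draw, max_length: int = 40, multi_partner: bool = False):
    """Random SecondaryStructure, possibly pseudoknotted."""
    length = draw(st.integers(min_value=2, max_value=max_length))
    n_pairs = draw(st.integers(min_value=0, max_value=length // 2))
    indices = list(range(length))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    pairs = set()
    used: set[int] = set()
    for _ in range(n_pairs):
        free = [i for i in indices if multi_partner or i not in used]
        if len(free) < 2:
            break
        i, j = rng.choice(free, size=2, replace=False)
        i, j = int(min(i, j)), int(max(i, j))
        if i == j or (i, j) in pairs:
            continue
        pairs.add((i, j))
        used.update((i, j))
    return SecondaryStructure(
        length=length, pairs=frozenset(pairs), multi_partner_allowed=multi_partner
    )


@st.composite
def torsion_arrays(draw, max_residues: int = 6):
    """Random well-formed per-residue torsion values (degrees)."""
    n = draw(st.integers(min_value=2, max_value=max_residues))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    cols = {
        nm: rng.uniform(-179.0, 179.0, n)
        for nm in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")
    }
    cols["alpha"][0] = np.nan
    cols["beta"][0] = np.nan
    cols["epsilon"][-1] = np.nan
    cols["zeta"][-1] = np.nan
    return cols


@pytest.fixture
def hairpin_graph() -> PairingGraph:
    """Single subunit, one 3-bp stem closed by a 4-nt loop."""
    return PairingGraph(
        segments=(
            SegmentSpec("stem5", (3, 3)),
            SegmentSpec("loop", (4, 4), role="loop"),
            SegmentSpec("stem3", (3, 3)),
        ),
        intra_edges=frozenset({("stem5", "stem3", "antiparallel")}),
    )


@pytest.fixture
def butterfly_graph() -> PairingGraph:
    """Two-fold pseudocycle: per subunit a plain hairpin, a kissing hairpin
    whose loop pairs with the next subunit's kissing loop, and a hinge;
    186 nt per subunit."""
    return PairingGraph(
        segments=(
            SegmentSpec("h1a", (25, 25)),
            SegmentSpec("loop1", (12, 12), role="loop"),
            SegmentSpec("h1b", (25, 25)),
            SegmentSpec("k5", (20, 20)),
            SegmentSpec("kiss", (16, 16)),
            SegmentSpec("k3", (20, 20)),
            SegmentSpec("hinge", (68, 68), role="hinge"),
        ),
        intra_edges=frozenset(
            {("h1a", "h1b", "antiparallel"), ("k5", "k3", "antiparallel")}
        ),
        inter_edges=frozenset({("kiss", "kiss", "antiparallel")}),
        symmetry_order=2,
        multi_partner=frozenset({"kiss"}),
    )
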