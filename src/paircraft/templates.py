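"""Pseudocycle secondary-structure templates from graph-level topology.

A *pseudocycle* is a single-chain RNA whose fold repeats a subunit ``n``
times with symmetric pairing between consecutive subunits.  The workflow:

1. describe one subunit as an ordered 5'->3' list of segments (helix sides,
   loops, hinges) with length bounds, plus intra-subunit partner edges;
2. propagate the subunit ``n`` times into a single chain and wire
   inter-subunit edges from subunit ``s`` to subunit ``(s+1) mod n``;
3. sample segment lengths from their bounds (partner segments share one
   draw), optionally rejection-sampling to a fixed total length;
4. realize the result as a :class:`~paircraft.secstruct.SecondaryStructure`
   and a :class:`~paircraft.conditioning.ConditioningTensor` ready for use
   as a generative-model conditioning input.

All subunits realize identical segment lengths, so rotating the global index
space by one subunit length is an automorphism of the pair map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import conditioning as cond
from .errors import FeasibilityError, SamplingError, TopologyError, ValidationError
from .secstruct import SecondaryStructure

Role = Literal["helix_side", "loop", "hinge"]


@dataclass(frozen=True)
class SegmentSpec:
    """One contiguous subunit segment with inclusive length bounds."""

    name: str
    length_bounds: tuple[int, int]
    role: Role = "helix_side"

    def __post_init__(self) -> None:
        lo, hi = self.length_bounds
        if not (1 <= lo <= hi):
            raise ValidationError(
                f"segment {self.name!r}: bounds must satisfy 1 <= min <= max, got {self.length_bounds}"
            )
        if self.role not in ("helix_side", "loop", "hinge"):
            raise ValidationError(f"segment {self.name!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class PairingGraph:
    """Coarse-grained topology of one subunit plus its symmetry order.

    ``intra_edges`` pair two segments within each subunit; ``inter_edges``
    pair a segment of subunit ``s`` with a segment of subunit ``(s+1) mod n``
    (kissing contacts between neighbours around the pseudocycle).  Edge
    tuples are ``(name_a, name_b, orientation)``; orientation defaults to
    antiparallel when omitted.
    """

    segments: tuple[SegmentSpec, ...]
    intra_edges: frozenset[tuple[str, str, str]] = frozenset()
    inter_edges: frozenset[tuple[str, str, str]] = frozenset()
    symmetry_order: int = 1
    multi_partner: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "intra_edges", frozenset(_norm_edge(e) for e in self.intra_edges))
        object.__setattr__(self, "inter_edges", frozenset(_norm_edge(e) for e in self.inter_edges))
        object.__setattr__(self, "multi_partner", frozenset(self.multi_partner))
        if self.symmetry_order < 1:
            raise ValidationError(f"symmetry_order must be >= 1, got {self.symmetry_order}")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate segment names in {names}")
        by_name = {s.name: s for s in self.segments}
        use_count: dict[str, int] = {}
        for a, b, _ in list(self.intra_edges) + list(self.inter_edges):
            for nm in (a, b):
                if nm not in by_name:
                    raise TopologyError(f"edge references unknown segment {nm!r}")
                use_count[nm] = use_count.get(nm, 0) + 1
            if by_name[a].length_bounds != by_name[b].length_bounds:
                raise TopologyError(
                    f"partner segments {a!r} and {b!r} have different length bounds"
                )
        for nm, c in use_count.items():
            if c > 1 and nm not in self.multi_partner:
                raise TopologyError(
                    f"segment {nm!r} appears in {c} edges but is not flagged multi-partner"
                )
        if self.symmetry_order == 1 and self.inter_edges:
            raise TopologyError(
                "inter-subunit edges reference a distinct subunit, "
                "but symmetry_order is 1"
            )

    @property
    def segment_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments)

    def by_name(self) -> dict[str, SegmentSpec]:
        return {s.name: s for s in self.segments}


def _norm_edge(e) -> tuple[str, str, str]:
    if len(e) == 2:
        return (e[0], e[1], "antiparallel")
    a, b, o = e
    if o not in ("antiparallel", "parallel"):
        raise ValidationError(f"unknown orientation {o!r} in edge {e}")
    return (a, b, o)


#: Global segment key: (subunit index, segment name).
SegKey = tuple[int, str]


@dataclass(frozen=True)
class ExpandedTopology:
    """Per-subunit segment list with edges lifted to global segment keys."""

    segments: tuple[tuple[SegKey, SegmentSpec], ...]
    edges: tuple[tuple[SegKey, SegKey, str], ...]
    symmetry_order: int


def propagate_symmetry(graph: PairingGraph) -> ExpandedTopology:
    """Replicate the subunit ``n`` times into a single 5'->3' chain.

    Intra edges are copied into every subunit; each inter edge connects
    subunit ``s`` to subunit ``(s+1) mod n``, so the last subunit wraps back
    to the first, closing the pseudocycle.
    """
    n = graph.symmetry_order
    segments: list[tuple[SegKey, SegmentSpec]] = []
    for s in range(n):
        for seg in graph.segments:
            segments.append(((s, seg.name), seg))
    edges: list[tuple[SegKey, SegKey, str]] = []
    for s in range(n):
        for a, b, o in sorted(graph.intra_edges):
            edges.append(((s, a), (s, b), o))
        for a, b, o in sorted(graph.inter_edges):
            edges.append(((s, a), ((s + 1) % n, b), o))
    return ExpandedTopology(tuple(segments), tuple(edges), n)


def _tie_groups(graph: PairingGraph) -> list[set[str]]:
    """Union segments that must realize equal lengths (edge partners)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.segment_names)
    for a, b, _ in list(graph.intra_edges) + list(graph.inter_edges):
        g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def sample_lengths(
    graph: PairingGraph,
    seed: int,
    target_total: int | None = None,
    max_tries: int = 10_000,
) -> dict[str, int]:
    """Draw one length per segment name, shared across subunits.

    Each tie group (segments linked by pairing edges, which must share
    bounds) receives a single uniform draw from its inclusive bounds.  With
    ``target_total`` set, whole assignments are rejection-sampled until
    ``n * sum(per-subunit lengths) == target_total``.

    Deterministic for a fixed (graph, seed, target_total).
    """
    n = graph.symmetry_order
    by_name = graph.by_name()
    groups = _tie_groups(graph)
    lo_total = n * sum(s.length_bounds[0] for s in graph.segments)
    hi_total = n * sum(s.length_bounds[1] for s in graph.segments)
    if target_total is not None and not (lo_total <= target_total <= hi_total):
        raise FeasibilityError(
            f"target_total {target_total} outside feasible range "
            f"[{lo_total}, {hi_total}]"
        )
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_tries + 1):
        lengths: dict[str, int] = {}
        for grp in sorted(groups, key=min):
            lo, hi = by_name[min(grp)].length_bounds
            val = int(rng.integers(lo, hi + 1))
            for nm in grp:
                lengths[nm] = val
        if target_total is None:
            return lengths
        total = n * sum(lengths[s.name] for s in graph.segments)
        if total == target_total:
            return lengths
    raise SamplingError(
        f"no assignment summing to {target_total} found in {max_tries} tries"
    )


@dataclass(frozen=True)
class TemplateRealization:
    """A realized pseudocycle template: per-segment intervals, the pair map
    as a single-chain secondary structure, and its conditioning tensor."""

    lengths: dict[str, int]
    intervals: dict[SegKey, tuple[int, int]]
    ss: SecondaryStructure
    tensor: cond.ConditioningTensor
    seed: int | None = None

    @property
    def total_length(self) -> int:
        return self.ss.length

    @property
    def subunit_length(self) -> int:
        n = max(s for s, _ in self.intervals) + 1
        return self.ss.length // n


def realize_template(
    graph: PairingGraph,
    lengths: dict[str, int],
    seed: int | None = None,
) -> TemplateRealization:
    """Lay segments onto global 0-based intervals and encode every edge.

    Segments are placed 5'->3' subunit by subunit; every edge becomes a
    :class:`~paircraft.conditioning.RegionPair` (helical duplexes are
    antiparallel unless the edge says otherwise).  Loop and hinge segments
    without edges stay unpaired.  Inter-subunit edges that cross
    intra-subunit helices produce pseudoknotted structures, which the
    dot-bracket writer expresses with extra bracket layers.
    """
    by_name = graph.by_name()
    for nm, val in lengths.items():
        lo, hi = by_name[nm].length_bounds
        if not (lo <= val <= hi):
            raise ValidationError(
                f"length {val} for segment {nm!r} outside bounds [{lo}, {hi}]"
            )
    topo = propagate_symmetry(graph)
    intervals: dict[SegKey, tuple[int, int]] = {}
    pos = 0
    for key, seg in topo.segments:
        w = lengths[seg.name]
        intervals[key] = (pos, pos + w)
        pos += w
    L = pos
    tensor = cond.ConditioningTensor(L)
    all_pairs: set[tuple[int, int]] = set()
    for key_a, key_b, orientation in topo.edges:
        rp = cond.RegionPair(
            region_a=intervals[key_a],
            region_b=intervals[key_b],
            orientation=orientation,
        )
        tensor = cond.encode_region_pair(tensor, rp)
        all_pairs |= rp.pair_set()
    counts: dict[int, int] = {}
    for i, j in all_pairs:
        counts[i] = counts.get(i, 0) + 1
        counts[j] = counts.get(j, 0) + 1
    multi = any(c > 1 for c in counts.values())
    ss = SecondaryStructure(length=L, pairs=frozenset(all_pairs), multi_partner_allowed=multi)
    return TemplateRealization(
        lengths=dict(lengths), intervals=intervals, ss=ss, tensor=tensor, seed=seed
    )


def generate_template(
    graph: PairingGraph,
    seed: int,
    target_total: int | None = None,
    max_tries: int = 10_000,
) -> TemplateRealization:
    """sample_lengths followed by realize_template (one-call convenience)."""
    lengths = sample_lengths(graph, seed, target_total=target_total, max_tries=max_tries)
    return realize_template(graph, lengths, seed=seed)


# -- topology config files ---------------------------------------------------


def load_topology(path) -> tuple[PairingGraph, dict]:
    """Load a YAML topology spec.

    Layout::

        symmetry_order: 2
        segments:
          - {name: stem5, length: [3, 5], role: helix_side}
          - {name: loop,  length: [4, 4], role: loop}
          - {name: stem3, length: [3, 5], role: helix_side}
        intra_edges:
          - [stem5, stem3, antiparallel]
        inter_edges: []
        target_total: 186        # optional
        seed: 7                  # optional

    Returns the graph plus a dict of the optional sampling keys
    (``target_total``, ``seed``).
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    segments = tuple(
        SegmentSpec(
            name=e["name"],
            length_bounds=tuple(e["length"]) if isinstance(e["length"], (list, tuple)) else (e["length"], e["length"]),
            role=e.get("role", "helix_side"),
        )
        for e in doc["segments"]
    )
    graph = PairingGraph(
        segments=segments,
        intra_edges=frozenset(tuple(e) for e in doc.get("intra_edges", []) or []),
        inter_edges=frozenset(tuple(e) for e in doc.get("inter_edges", []) or []),
        symmetry_order=int(doc.get("symmetry_order", 1)),
        multi_partner=frozenset(doc.get("multi_partner", []) or []),
    )
    opts = {k: doc[k] for k in ("target_total", "seed") if k in doc}
    return graph, opts
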