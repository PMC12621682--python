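"""Three-channel base-pair conditioning tensors.

The constraint array ``A`` is L x L x 3 one-hot with channel semantics

* ``[1,0,0]`` unspecified (no constraint),
* ``[0,1,0]`` explicitly non-pairing,
* ``[0,0,1]`` paired,

symmetric in (i, j) with the diagonal pinned to *unspecified*.  Region-level
helpers place paired cells of two equal-width regions on the submatrix
diagonal (parallel strands) or anti-diagonal (antiparallel strands), which is
how strand orientation is expressed without any extra feature channel.

Internally the tensor is stored as an L x L uint8 channel-index matrix
(0 = unspecified, 1 = non-pairing, 2 = paired); ``to_array`` expands to the
one-hot form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import ConflictError, ValidationError
from .secstruct import SecondaryStructure

UNSPECIFIED, NONPAIRING, PAIRED = 0, 1, 2
_CHANNEL_NAMES = {0: "unspecified", 1: "nonpairing", 2: "paired"}

Orientation = Literal["antiparallel", "parallel"]


@dataclass(frozen=True)
class RegionPair:
    """Two equal-width, non-overlapping half-open index intervals to be
    paired base-by-base, with explicit strand orientation.

    ``antiparallel`` pairs ``a_start+k`` with ``b_end-1-k`` (anti-diagonal
    submatrix); ``parallel`` pairs ``a_start+k`` with ``b_start+k`` (diagonal
    submatrix).
    """

    region_a: tuple[int, int]
    region_b: tuple[int, int]
    orientation: Orientation = "antiparallel"

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1) = self.region_a, self.region_b
        if not (0 <= a0 < a1 and 0 <= b0 < b1):
            raise ValidationError(f"empty or negative region: {self.region_a}, {self.region_b}")
        if (a1 - a0) != (b1 - b0):
            raise ValidationError(
                f"region widths differ: {a1 - a0} vs {b1 - b0}"
            )
        if max(a0, b0) < min(a1, b1):
            raise ValidationError(
                f"regions overlap: {self.region_a} and {self.region_b}"
            )
        if self.orientation not in ("antiparallel", "parallel"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def width(self) -> int:
        return self.region_a[1] - self.region_a[0]

    def pair_set(self) -> frozenset[tuple[int, int]]:
        """The (i, j) base pairs (i < j) this region pair induces."""
        (a0, _), (b0, b1) = self.region_a, self.region_b
        w = self.width
        if self.orientation == "antiparallel":
            raw = ((a0 + k, b1 - 1 - k) for k in range(w))
        else:
            raw = ((a0 + k, b0 + k) for k in range(w))
        return frozenset((min(i, j), max(i, j)) for i, j in raw)


class ConditioningTensor:
    """Symmetric one-hot pair-constraint tensor over ``L`` nucleotides."""

    def __init__(self, L: int, chain_breaks: tuple[int, ...] = ()):
        if L <= 0:
            raise ValidationError(f"tensor size must be positive, got {L}")
        self.L = int(L)
        self.chain_breaks = tuple(sorted(chain_breaks))
        self._m = np.zeros((L, L), dtype=np.uint8)

    # -- core cell operations ---------------------------------------------

    def _set_cell(self, i: int, j: int, channel: int) -> None:
        if not (0 <= i < self.L and 0 <= j < self.L):
            raise ValidationError(f"cell ({i}, {j}) out of range for L={self.L}")
        if i == j:
            raise ValidationError(f"diagonal cell ({i}, {i}) must stay unspecified")
        cur = int(self._m[i, j])
        if cur != UNSPECIFIED and cur != channel:
            raise ConflictError(
                f"cell ({i}, {j}) already {_CHANNEL_NAMES[cur]}, "
                f"refusing to overwrite with {_CHANNEL_NAMES[channel]}"
            )
        self._m[i, j] = channel
        self._m[j, i] = channel

    def set_paired(self, i: int, j: int) -> None:
        self._set_cell(i, j, PAIRED)

    def set_nonpairing(self, i: int, j: int) -> None:
        self._set_cell(i, j, NONPAIRING)

    def channel(self, i: int, j: int) -> int:
        return int(self._m[i, j])

    # -- views -------------------------------------------------------------

    def to_array(self) -> np.ndarray:
        """Expand to the L x L x 3 one-hot uint8 array."""
        return np.eye(3, dtype=np.uint8)[self._m]

    @classmethod
    def from_array(cls, A: np.ndarray, chain_breaks: tuple[int, ...] = ()) -> "ConditioningTensor":
        """Build from an L x L x 3 one-hot array, validating one-hotness,
        symmetry and the unspecified diagonal."""
        A = np.asarray(A)
        if A.ndim != 3 or A.shape[0] != A.shape[1] or A.shape[2] != 3:
            raise ValidationError(f"expected (L, L, 3) array, got {A.shape}")
        if not np.all(A.sum(axis=2) == 1) or not np.all((A == 0) | (A == 1)):
            raise ValidationError("tensor cells are not one-hot")
        m = np.argmax(A, axis=2).astype(np.uint8)
        if not np.array_equal(m, m.T):
            raise ValidationError("tensor is not symmetric")
        if np.any(np.diag(m) != UNSPECIFIED):
            raise ValidationError("diagonal cells must be unspecified")
        t = cls(A.shape[0], chain_breaks)
        t._m = m
        return t

    def validate(self) -> None:
        """Re-check symmetry and the unspecified diagonal."""
        if not np.array_equal(self._m, self._m.T):
            raise ValidationError("tensor is not symmetric")
        if np.any(np.diag(self._m) != UNSPECIFIED):
            raise ValidationError("diagonal cells must be unspecified")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ConditioningTensor)
            and self.L == other.L
            and self.chain_breaks == other.chain_breaks
            and np.array_equal(self._m, other._m)
        )

    def copy(self) -> "ConditioningTensor":
        t = ConditioningTensor(self.L, self.chain_breaks)
        t._m = self._m.copy()
        return t

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Save as a portable NumPy ``.npz`` container: the uint8 channel
        matrix plus L and chain_breaks."""
        np.savez(
            path,
            channels=self._m,
            L=np.array(self.L),
            chain_breaks=np.array(self.chain_breaks, dtype=np.int64),
        )

    @classmethod
    def load(cls, path) -> "ConditioningTensor":
        with np.load(path) as z:
            t = cls(int(z["L"]), tuple(int(b) for b in z["chain_breaks"]))
            m = z["channels"].astype(np.uint8)
        if m.shape != (t.L, t.L):
            raise ValidationError(f"channel matrix shape {m.shape} != ({t.L}, {t.L})")
        t._m = m
        t.validate()
        return t

    def save_sparse(self, path) -> None:
        """Sparse text export: header comments then 'i<TAB>j<TAB>channel'
        lines for every constrained upper-triangle cell."""
        with open(path, "w") as fh:
            fh.write(f"# L={self.L}\n")
            fh.write("# chain_breaks=" + ",".join(map(str, self.chain_breaks)) + "\n")
            fh.write("# i\tj\tchannel (1=nonpairing, 2=paired)\n")
            ii, jj = np.nonzero(np.triu(self._m))
            for i, j in zip(ii.tolist(), jj.tolist()):
                fh.write(f"{i}\t{j}\t{int(self._m[i, j])}\n")

    @classmethod
    def load_sparse(cls, path) -> "ConditioningTensor":
        L = None
        breaks: tuple[int, ...] = ()
        cells: list[tuple[int, int, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("L="):
                        L = int(body[2:])
                    elif body.startswith("chain_breaks="):
                        val = body.split("=", 1)[1].strip()
                        breaks = tuple(int(x) for x in val.split(",")) if val else ()
                    continue
                i, j, c = (int(x) for x in line.split()[:3])
                cells.append((i, j, c))
        if L is None:
            raise ValidationError("sparse tensor file lacks '# L=' header")
        t = cls(L, breaks)
        for i, j, c in cells:
            t._set_cell(i, j, c)
        return t


# -- operations -------------------------------------------------------------


def encode_pairs(
    L: int,
    paired: Iterable[tuple[int, int]],
    nonpaired: Iterable[tuple[int, int]] = (),
    chain_breaks: tuple[int, ...] = (),
) -> ConditioningTensor:
    """Encode explicit paired and non-pairing index pairs into a fresh tensor.

    Each listed cell and its mirror get the corresponding channel; everything
    else, including the diagonal, stays unspecified.  A cell appearing in both
    sets raises :class:`ConflictError`.
    """
    t = ConditioningTensor(L, chain_breaks)
    for i, j in paired:
        t.set_paired(i, j)
    for i, j in nonpaired:
        t.set_nonpairing(i, j)
    return t


def encode_region_pair(tensor: ConditioningTensor, rp: RegionPair) -> ConditioningTensor:
    """Add one region pair's base pairs to a copy of ``tensor``.

    Antiparallel regions land on the anti-diagonal of the region_a x region_b
    submatrix, parallel regions on its main diagonal.  Multiple region pairs
    may accumulate on one tensor; a base may gain several partners
    (triplex / quadruplex support).  Re-adding an identical region pair is a
    no-op (cells already ``paired`` stay ``paired``).
    """
    for (s, e) in (rp.region_a, rp.region_b):
        if not (0 <= s < e <= tensor.L):
            raise ValidationError(f"region [{s}, {e}) outside tensor of size {tensor.L}")
    out = tensor.copy()
    for i, j in rp.pair_set():
        out.set_paired(i, j)
    return out


def decode_tensor(
    tensor: ConditioningTensor,
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """Return the (paired, nonpairing) upper-triangle cell sets.

    ``encode_pairs(L, *decode_tensor(A))`` reproduces ``A`` exactly.
    """
    tensor.validate()
    iu, ju = np.triu_indices(tensor.L, k=1)
    vals = tensor._m[iu, ju]
    paired = frozenset(zip(iu[vals == PAIRED].tolist(), ju[vals == PAIRED].tolist()))
    nonpaired = frozenset(zip(iu[vals == NONPAIRING].tolist(), ju[vals == NONPAIRING].tolist()))
    return paired, nonpaired


def from_secondary_structure(
    ss: SecondaryStructure, unpaired_as_nonpairing: bool = False
) -> ConditioningTensor:
    """Convert a secondary structure to a conditioning tensor.

    Every base pair becomes a ``paired`` cell.  With ``unpaired_as_nonpairing``
    every off-diagonal cell (i, j) where *both* positions are unpaired becomes
    ``non-pairing`` (loop enforcement); otherwise those cells stay
    unspecified.
    """
    t = ConditioningTensor(ss.length, ss.chain_breaks)
    for i, j in ss.pairs:
        t.set_paired(i, j)
    if unpaired_as_nonpairing:
        unpaired = sorted(ss.unpaired_indices())
        for a_idx, i in enumerate(unpaired):
            for j in unpaired[a_idx + 1:]:
                t.set_nonpairing(i, j)
    return t


def strand_exchange_template(
    chain_lengths: list[int],
    duplex_blocks: list[tuple[int, tuple[int, int], int, tuple[int, int], Orientation]],
) -> tuple[ConditioningTensor, SecondaryStructure]:
    """Build a multi-chain pairing template with strand exchange.

    Each duplex block ``(chain_a, interval_a, chain_b, interval_b,
    orientation)`` pairs two intra-chain intervals base-by-base; chains are
    concatenated in listed order into one global index space with
    ``chain_breaks`` at the junctions.  A chain may appear in blocks with two
    or more distinct partners — that is the Holliday-junction-like strand
    exchange topology.

    Returns the conditioning tensor and the equivalent multi-chain
    :class:`SecondaryStructure`.
    """
    if not chain_lengths or any(n <= 0 for n in chain_lengths):
        raise ValidationError(f"chain lengths must be positive: {chain_lengths}")
    offsets = np.concatenate([[0], np.cumsum(chain_lengths)])
    L = int(offsets[-1])
    breaks = tuple(int(o) for o in offsets[1:-1])
    tensor = ConditioningTensor(L, breaks)
    all_pairs: set[tuple[int, int]] = set()
    for chain_a, (a0, a1), chain_b, (b0, b1), orientation in duplex_blocks:
        for chain, (s, e) in ((chain_a, (a0, a1)), (chain_b, (b0, b1))):
            if not (0 <= chain < len(chain_lengths)):
                raise ValidationError(f"no chain {chain}")
            if not (0 <= s < e <= chain_lengths[chain]):
                raise ValidationError(
                    f"interval [{s}, {e}) exceeds chain {chain} "
                    f"of length {chain_lengths[chain]}"
                )
        rp = RegionPair(
            region_a=(int(offsets[chain_a]) + a0, int(offsets[chain_a]) + a1),
            region_b=(int(offsets[chain_b]) + b0, int(offsets[chain_b]) + b1),
            orientation=orientation,
        )
        tensor = encode_region_pair(tensor, rp)
        all_pairs |= rp.pair_set()
    counts: dict[int, int] = {}
    for i, j in all_pairs:
        counts[i] = counts.get(i, 0) + 1
        counts[j] = counts.get(j, 0) + 1
    multi = any(c > 1 for c in counts.values())
    ss = SecondaryStructure(
        length=L, pairs=frozenset(all_pairs), chain_breaks=breaks,
        multi_partner_allowed=multi,
    )
    return tensor, ss


# -- region-pair config files ------------------------------------------------


def load_region_pairs(path) -> list[RegionPair]:
    """Load region pairs from a YAML list of
    ``{region_a: [s, e], region_b: [s, e], orientation: ...}`` entries."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, list):
        raise ValidationError("region-pair config must be a YAML list")
    out = []
    for entry in doc:
        out.append(
            RegionPair(
                region_a=tuple(entry["region_a"]),
                region_b=tuple(entry["region_b"]),
                orientation=entry.get("orientation", "antiparallel"),
            )
        )
    return out
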