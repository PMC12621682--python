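"""Nucleic-acid secondary structures with arbitrary-order pseudoknots.

A structure is a set of base-pair index tuples over ``length`` nucleotides,
optionally split into several chains.  Pseudoknots (crossing pairs) are
expressed in dot-bracket notation with multiple bracket alphabets: pairs in
the first layer use ``()``, crossing pairs spill into ``[]``, ``{}``, ``<>``
and then letter pairs ``Aa`` .. ``Zz``.

Indexing is 0-based throughout and chain separators (``&`` or ``+``) are not
counted as positions.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import CapacityError, ParseError, UnrepresentableError, ValidationError

#: Bracket alphabet in layer order: the community multi-bracket dialect.
DEFAULT_ALPHABET: tuple[tuple[str, str], ...] = (
    ("(", ")"),
    ("[", "]"),
    ("{", "}"),
    ("<", ">"),
) + tuple((u, l) for u, l in zip(string.ascii_uppercase, string.ascii_lowercase))

CHAIN_SEPARATORS = ("&", "+")


@dataclass(frozen=True)
class SecondaryStructure:
    """A base-pair set over one or more concatenated chains.

    Parameters
    ----------
    length
        Total nucleotide count over all chains.
    pairs
        Set of ``(i, j)`` tuples with ``0 <= i < j < length``.
    chain_breaks
        Sorted 0-based indices at which a new chain starts (never 0).
    multi_partner_allowed
        Permit one index to appear in several pairs (triplex / quadruplex
        pair sets).  Such structures cannot be written as dot-bracket.
    """

    length: int
    pairs: frozenset[tuple[int, int]] = frozenset()
    chain_breaks: tuple[int, ...] = ()
    multi_partner_allowed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        object.__setattr__(self, "chain_breaks", tuple(sorted(self.chain_breaks)))
        self.validate()

    def validate(self) -> None:
        if self.length < 0:
            raise ValidationError(f"negative length {self.length}")
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise ValidationError(f"self-pair ({i}, {j})")
            if not (0 <= i < j < self.length):
                raise ValidationError(
                    f"pair ({i}, {j}) out of range for length {self.length}"
                )
            if not self.multi_partner_allowed:
                for k in (i, j):
                    if k in seen:
                        raise ValidationError(
                            f"index {k} paired more than once "
                            "(set multi_partner_allowed to permit this)"
                        )
                seen.update((i, j))
        for b in self.chain_breaks:
            if not (0 < b < self.length):
                raise ValidationError(f"chain break {b} out of range (0, {self.length})")

    # -- convenience -------------------------------------------------------

    @property
    def n_chains(self) -> int:
        return len(self.chain_breaks) + 1

    def partner_map(self) -> dict[int, list[int]]:
        """Map each paired index to its (sorted) partner list."""
        out: dict[int, list[int]] = {}
        for i, j in self.pairs:
            out.setdefault(i, []).append(j)
            out.setdefault(j, []).append(i)
        return {k: sorted(v) for k, v in out.items()}

    def paired_indices(self) -> set[int]:
        return {k for p in self.pairs for k in p}

    def unpaired_indices(self) -> set[int]:
        return set(range(self.length)) - self.paired_indices()


def _crossing(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True if pairs p and q cross (i < k < j < l in either order)."""
    (i, j), (k, l) = sorted((p, q))
    return i < k < j < l


def _greedy_layers(pairs: Iterable[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """Assign each pair the lowest layer free of crossings with earlier pairs.

    Pairs are processed by ascending opener index (then closer), which makes
    the assignment deterministic.  Greedy colouring of the crossing graph, not
    a minimal colouring.
    """
    layers: dict[tuple[int, int], int] = {}
    by_layer: list[list[tuple[int, int]]] = []
    for p in sorted(pairs):
        lvl = 0
        while lvl < len(by_layer) and any(_crossing(p, q) for q in by_layer[lvl]):
            lvl += 1
        if lvl == len(by_layer):
            by_layer.append([])
        by_layer[lvl].append(p)
        layers[p] = lvl
    return layers


def parse_dotbracket(
    s: str,
    alphabet: Sequence[tuple[str, str]] = DEFAULT_ALPHABET,
) -> SecondaryStructure:
    """Parse a (possibly pseudoknotted, multi-chain) dot-bracket string.

    Each bracket layer is matched with its own stack, so layers are fully
    independent; ``&`` / ``+`` start a new chain and do not consume an index.

    Raises
    ------
    ParseError
        On an unknown character or an unbalanced bracket in any layer, naming
        the layer and string position.
    """
    openers = {o: lvl for lvl, (o, _) in enumerate(alphabet)}
    closers = {c: lvl for lvl, (_, c) in enumerate(alphabet)}
    stacks: dict[int, list[int]] = {lvl: [] for lvl in range(len(alphabet))}
    pairs: set[tuple[int, int]] = set()
    chain_breaks: list[int] = []
    idx = 0
    for pos, ch in enumerate(s):
        if ch == ".":
            idx += 1
        elif ch in CHAIN_SEPARATORS:
            chain_breaks.append(idx)
        elif ch in openers:
            stacks[openers[ch]].append(idx)
            idx += 1
        elif ch in closers:
            lvl = closers[ch]
            if not stacks[lvl]:
                raise ParseError(
                    f"unbalanced '{ch}' (layer {lvl}) at string position {pos}: "
                    "closer without opener"
                )
            pairs.add((stacks[lvl].pop(), idx))
            idx += 1
        else:
            raise ParseError(f"unknown character {ch!r} at string position {pos}")
    for lvl, stack in stacks.items():
        if stack:
            raise ParseError(
                f"unbalanced '{alphabet[lvl][0]}' (layer {lvl}): "
                f"{len(stack)} opener(s) never closed (first at index {stack[0]})"
            )
    breaks = [b for b in chain_breaks if 0 < b < idx]
    return SecondaryStructure(length=idx, pairs=frozenset(pairs), chain_breaks=tuple(breaks))


def write_dotbracket(
    ss: SecondaryStructure,
    alphabet: Sequence[tuple[str, str]] = DEFAULT_ALPHABET,
) -> str:
    """Serialize to dot-bracket, assigning crossing pairs to extra layers.

    Layer assignment is the deterministic greedy colouring used throughout
    the package; ``parse_dotbracket(write_dotbracket(ss)) == ss``.

    Raises
    ------
    UnrepresentableError
        If any index has more than one partner (base triples have no
        dot-bracket form).
    CapacityError
        If the greedy layering needs more layers than the alphabet has.
    """
    if ss.multi_partner_allowed:
        partners = ss.partner_map()
        bad = {k for k, v in partners.items() if len(v) > 1}
        if bad:
            raise UnrepresentableError(
                f"indices {sorted(bad)} have multiple partners; "
                "dot-bracket cannot express base triples"
            )
    layers = _greedy_layers(ss.pairs)
    n_layers = max(layers.values(), default=-1) + 1
    if n_layers > len(alphabet):
        raise CapacityError(
            f"{n_layers} bracket layers required but alphabet has {len(alphabet)}"
        )
    chars = ["."] * ss.length
    for (i, j), lvl in layers.items():
        chars[i] = alphabet[lvl][0]
        chars[j] = alphabet[lvl][1]
    for b in reversed(ss.chain_breaks):
        chars.insert(b, "&")
    return "".join(chars)


def pseudoknot_order(ss: SecondaryStructure) -> int:
    """Bracket layers required by the greedy layering, minus one.

    0 for fully nested (or empty) structures; 1 for a simple kissing-loop
    pseudoknot; higher for deeper crossing topologies.
    """
    layers = _greedy_layers(ss.pairs)
    return max(layers.values(), default=0)


# -- file I/O ---------------------------------------------------------------


def read_dotbracket_file(path) -> list[tuple[str, str | None, SecondaryStructure]]:
    """Read a dot-bracket file: records of '>name', optional sequence line,
    structure line.  Returns (name, sequence-or-None, structure) triples."""
    records: list[tuple[str, str | None, SecondaryStructure]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if lines and not lines[0].startswith(">"):
        raise ParseError("expected '>' header on the first line")
    # group body lines per record: one body line = structure only,
    # two = sequence then structure
    i = 0
    while i < len(lines):
        name = lines[i][1:].strip()
        body: list[str] = []
        i += 1
        while i < len(lines) and not lines[i].startswith(">"):
            body.append(lines[i])
            i += 1
        if not body or len(body) > 2:
            raise ParseError(
                f"record {name!r} needs a structure line "
                "(optionally preceded by one sequence line)"
            )
        seq = body[0] if len(body) == 2 else None
        records.append((name, seq, parse_dotbracket(body[-1])))
    return records


def write_dotbracket_file(path, records) -> None:
    """Write (name, sequence-or-None, structure) records as a dot-bracket file."""
    with open(path, "w") as fh:
        for name, seq, ss in records:
            fh.write(f">{name}\n")
            if seq is not None:
                fh.write(seq + "\n")
            fh.write(write_dotbracket(ss) + "\n")


def read_pair_table(path) -> SecondaryStructure:
    """Read a tab-separated pair table: columns i, j (0-based), '#' comments.

    An optional header comment ``# length=N`` fixes the total length;
    otherwise length is max index + 1.  ``# chain_breaks=a,b`` is honoured
    the same way.
    """
    pairs: set[tuple[int, int]] = set()
    length: int | None = None
    breaks: tuple[int, ...] = ()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("length="):
                    length = int(body.split("=", 1)[1])
                elif body.startswith("chain_breaks="):
                    val = body.split("=", 1)[1].strip()
                    breaks = tuple(int(x) for x in val.split(",")) if val else ()
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected two columns, got {line!r}")
            i, j = int(fields[0]), int(fields[1])
            pairs.add((min(i, j), max(i, j)))
    if length is None:
        length = max((j for _, j in pairs), default=-1) + 1
    counts: dict[int, int] = {}
    for i, j in pairs:
        counts[i] = counts.get(i, 0) + 1
        counts[j] = counts.get(j, 0) + 1
    multi = any(c > 1 for c in counts.values())
    return SecondaryStructure(
        length=length, pairs=frozenset(pairs), chain_breaks=breaks,
        multi_partner_allowed=multi,
    )


def write_pair_table(path, ss: SecondaryStructure) -> None:
    """Write a secondary structure as a tab-separated 0-based pair table."""
    with open(path, "w") as fh:
        fh.write(f"# length={ss.length}\n")
        if ss.chain_breaks:
            fh.write("# chain_breaks=" + ",".join(map(str, ss.chain_breaks)) + "\n")
        fh.write("# i\tj\n")
        for i, j in sorted(ss.pairs):
            fh.write(f"{i}\t{j}\n")
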