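"""Parsing and formatting of BRS-relative mutation tokens.

The field's shorthand writes each sequence change relative to the reference
as a position with optional decorations: plain digits denote a transition
(``169``); a trailing base denotes a transversion to that base (``15953G``);
``+`` followed by bases denotes an insertion after the position (``221+C``);
a trailing ``d`` denotes a single-position deletion (``271d``).  A ``(h)``
suffix marks heteroplasmy.  On trees, an ``@`` prefix marks a recurrent hit
and a superscript-beta prefix marks a true back mutation with respect to
evolutionary direction; both are display annotations that do not change the
identity of the mutation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "Mutation",
    "MutationSet",
    "MutationParseError",
    "parse_token",
    "parse_motif",
    "format_mutation",
    "transition_partner",
    "UNSTABLE_POSITIONS",
]

#: Control-region sites the literature treats as mutationally unstable and
#: therefore non-diagnostic on their own; they score at half weight.
UNSTABLE_POSITIONS = frozenset({169})

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

_TOKEN_RE = re.compile(
    r"^(?P<prefix>@|β|\^β)?"
    r"(?P<pos>\d+)"
    r"(?P<suffix>[ACGT]|\+[ACGT]+|d)?"
    r"(?P<het>\(h\))?$"
)


class MutationParseError(ValueError):
    """A mutation token does not match the notation grammar."""


def transition_partner(base: str) -> str:
    """The transition partner of a base (A<->G, C<->T)."""
    try:
        return _TRANSITION_PARTNER[base.upper()]
    except KeyError:
        raise ValueError(f"not a nucleotide: {base!r}") from None


@dataclass(frozen=True)
class Mutation:
    """One BRS-relative sequence change.

    ``derived_base`` is set only for transversions (the explicit base of the
    token); transitions leave it ``None`` because the derived allele is
    implied by the reference base.  ``inserted_seq`` holds the bases of an
    insertion, placed *after* ``position``.
    """

    position: int
    kind: str  # transition | transversion | insertion | deletion
    derived_base: str | None = None
    inserted_seq: str | None = None
    heteroplasmic: bool = False
    back_mutation: bool = False
    recurrent: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.kind not in ("transition", "transversion", "insertion", "deletion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "transversion" and not self.derived_base:
            raise ValueError("transversion requires a derived base")
        if self.kind == "transition" and self.derived_base:
            raise ValueError("transition carries no explicit base")
        if self.kind == "insertion" and not self.inserted_seq:
            raise ValueError("insertion requires inserted bases")

    @property
    def key(self) -> tuple:
        """Identity key: display prefixes and heteroplasmy do not count."""
        return (self.position, self.kind, self.derived_base, self.inserted_seq)

    @property
    def weight(self) -> float:
        """Diagnostic weight used by the motif classifier."""
        return 0.5 if self.position in UNSTABLE_POSITIONS else 1.0

    def token(self) -> str:
        return format_mutation(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


def parse_token(token: str) -> Mutation:
    """Parse one mutation token into a :class:`Mutation`.

    >>> parse_token("16057C").kind
    'transversion'
    >>> parse_token("221+C").inserted_seq
    'C'
    >>> parse_token("169").kind
    'transition'
    """
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise MutationParseError(f"malformed mutation token: {token!r}")
    pos = int(m.group("pos"))
    suffix = m.group("suffix")
    prefix = m.group("prefix")
    het = m.group("het") is not None
    back = prefix in ("β", "^β")
    recur = prefix == "@"
    if suffix is None:
        return Mutation(pos, "transition", heteroplasmic=het,
                        back_mutation=back, recurrent=recur)
    if suffix == "d":
        return Mutation(pos, "deletion", heteroplasmic=het,
                        back_mutation=back, recurrent=recur)
    if suffix.startswith("+"):
        return Mutation(pos, "insertion", inserted_seq=suffix[1:],
                        heteroplasmic=het, back_mutation=back, recurrent=recur)
    return Mutation(pos, "transversion", derived_base=suffix,
                    heteroplasmic=het, back_mutation=back, recurrent=recur)


def format_mutation(m: Mutation) -> str:
    """Canonical token for a mutation; inverse of :func:`parse_token`."""
    prefix = "β" if m.back_mutation else "@" if m.recurrent else ""
    if m.kind == "transition":
        core = str(m.position)
    elif m.kind == "transversion":
        core = f"{m.position}{m.derived_base}"
    elif m.kind == "insertion":
        core = f"{m.position}+{m.inserted_seq}"
    else:
        core = f"{m.position}d"
    return f"{prefix}{core}" + ("(h)" if m.heteroplasmic else "")


@dataclass(frozen=True)
class MutationSet:
    """An ordered, duplicate-free collection of mutations.

    Stored strictly ascending by position (display wrap order for the
    control region is an output-formatting concern, handled in io).
    """

    mutations: tuple[Mutation, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.mutations, key=lambda m: (m.position, m.kind, m.derived_base or "", m.inserted_seq or ""))
        )
        keys = [m.key for m in ordered]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate mutations in set: {dupes}")
        object.__setattr__(self, "mutations", ordered)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "MutationSet":
        return cls(tuple(parse_token(t) for t in tokens))

    def __iter__(self) -> Iterator[Mutation]:
        return iter(self.mutations)

    def __len__(self) -> int:
        return len(self.mutations)

    def __contains__(self, item) -> bool:
        if isinstance(item, Mutation):
            return item.key in self._keys
        return False

    @property
    def _keys(self) -> frozenset:
        return frozenset(m.key for m in self.mutations)

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def union(self, other: "MutationSet") -> "MutationSet":
        extra = [m for m in other if m.key not in self._keys]
        return MutationSet(self.mutations + tuple(extra))

    def difference(self, other: "MutationSet") -> "MutationSet":
        return MutationSet(tuple(m for m in self if m.key not in other._keys))

    def symmetric_difference(self, other: "MutationSet") -> "MutationSet":
        return self.difference(other).union(other.difference(self))

    def intersection(self, other: "MutationSet") -> "MutationSet":
        return MutationSet(tuple(m for m in self if m.key in other._keys))

    def __eq__(self, other) -> bool:
        if not isinstance(other, MutationSet):
            return NotImplemented
        return self._keys == other._keys

    def __hash__(self) -> int:
        return hash(self._keys)

    def motif_string(self, separator: str = "-") -> str:
        return separator.join(format_mutation(m) for m in self.mutations)


def parse_motif(motif: str, separator: str = "-") -> MutationSet:
    """Parse a motif string like ``"169-15953G-16255"`` into a MutationSet.

    The empty string denotes the reference haplotype itself (an empty set);
    duplicate tokens are a validation error.
    """
    motif = motif.strip()
    if not motif:
        return MutationSet()
    tokens = motif.split(separator)
    if any(not t for t in tokens):
        raise MutationParseError(f"empty token in motif {motif!r}")
    muts = [parse_token(t) for t in tokens]
    keys = [m.key for m in muts]
    if len(set(keys)) != len(keys):
        raise MutationParseError(f"duplicate token in motif {motif!r}")
    return MutationSet(tuple(muts))
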