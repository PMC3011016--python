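"""Circular-coordinate arithmetic on the bovine mitochondrial reference frame.

All positions are 1-based "np" (nucleotide position) numbers on the Bovine
Reference Sequence (BRS) frame, the convention used throughout the bovine
mtDNA literature.  The mitochondrial genome is circular, so a region window
may wrap through the origin (e.g. the control region read window np
15823-215).  Conversions to half-open 0-based indices are private to this
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "BRS_LENGTH",
    "CONTROL_WINDOW",
    "CODING_WINDOW",
    "ReferenceGenome",
    "RegionWindow",
    "window_length",
    "position_in_window",
    "load_reference",
]

#: Length of the BRS (GenBank V00654) in bp.
BRS_LENGTH = 16338

_VALID_REF = set("ACGT")
_VALID_QUERY = set("ACGTN")


class CoordinateError(ValueError):
    """A position or window falls outside the reference frame."""


@dataclass(frozen=True)
class RegionWindow:
    """Closed 1-based interval on a circular genome.

    When ``circular`` and ``end_np < start_np`` the window wraps through the
    origin (np L -> np 1).
    """

    start_np: int
    end_np: int
    circular: bool = True

    def __post_init__(self) -> None:
        if self.start_np < 1 or self.end_np < 1:
            raise CoordinateError(
                f"window positions must be >= 1, got {self.start_np}-{self.end_np}"
            )
        if self.end_np < self.start_np and not self.circular:
            raise CoordinateError(
                f"non-circular window cannot wrap: {self.start_np}-{self.end_np}"
            )

    @property
    def wraps(self) -> bool:
        return self.circular and self.end_np < self.start_np

    def validate(self, genome_length: int) -> None:
        if self.start_np > genome_length or self.end_np > genome_length:
            raise CoordinateError(
                f"window {self.start_np}-{self.end_np} exceeds genome length "
                f"{genome_length}"
            )


#: Control-region read window: "at least 730 bp, from np 15823 to np 215".
CONTROL_WINDOW = RegionWindow(15823, 215)

#: Coding-region window over which the molecular clock is defined (15,428 bp).
CODING_WINDOW = RegionWindow(364, 15791)


@dataclass(frozen=True)
class ReferenceGenome:
    """A circular nucleotide reference with an identifier.

    The reference alphabet is strictly A/C/G/T; ambiguity codes are allowed
    in queries but never in the reference itself.
    """

    id: str
    sequence: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "length", len(seq))
        bad = set(seq) - _VALID_REF
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")
        if not seq:
            raise ValueError("reference sequence is empty")

    def base_at(self, np_: int) -> str:
        """Reference base at 1-based position ``np_``."""
        if not 1 <= np_ <= self.length:
            raise CoordinateError(f"np {np_} outside [1, {self.length}]")
        return self.sequence[np_ - 1]

    def window_positions(self, window: RegionWindow) -> list[int]:
        """The ordered np positions covered by ``window``."""
        window.validate(self.length)
        if window.wraps:
            return list(range(window.start_np, self.length + 1)) + list(
                range(1, window.end_np + 1)
            )
        return list(range(window.start_np, window.end_np + 1))

    def window_sequence(self, window: RegionWindow) -> str:
        window.validate(self.length)
        if window.wraps:
            return self.sequence[window.start_np - 1 :] + self.sequence[: window.end_np]
        return self.sequence[window.start_np - 1 : window.end_np]


def window_length(window: RegionWindow, genome_length: int) -> int:
    """Length in bp of a (possibly wrapping) closed window.

    >>> window_length(RegionWindow(15823, 215), 16338)
    731
    """
    window.validate(genome_length)
    if window.wraps:
        return (genome_length - window.start_np + 1) + window.end_np
    return window.end_np - window.start_np + 1


def position_in_window(np_: int, window: RegionWindow, genome_length: int | None = None) -> bool:
    """True iff 1-based ``np_`` lies in the (possibly wrapping) closed window."""
    if np_ < 1 or (genome_length is not None and np_ > genome_length):
        raise CoordinateError(f"np {np_} outside [1, {genome_length}]")
    if window.wraps:
        return np_ >= window.start_np or np_ <= window.end_np
    return window.start_np <= np_ <= window.end_np


def load_reference(path, record_id: str | None = None) -> ReferenceGenome:
    """Load a single-record FASTA reference."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single-record FASTA, found {len(records)} records")
    rec = records[0]
    return ReferenceGenome(id=record_id or rec.id, sequence=str(rec.seq))
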