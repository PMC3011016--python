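"""Variant calling against the reference window, and its inverse.

``call_variants`` turns a raw sequence into the set of BRS-relative
mutations it carries over a stated covered window, via global pairwise
alignment.  ``apply_mutations`` edits the reference window by a mutation
set, so that synthetic sequences can be generated and the two operations
round-trip.  Indels are reported at their 3'-most equivalent placement
within homopolymer runs, the standard mtDNA nomenclature convention.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .mutation import Mutation, MutationSet, transition_partner
from .reference import ReferenceGenome, RegionWindow, position_in_window

__all__ = ["VariantProfile", "call_variants", "apply_mutations", "NotAlignableError"]


class NotAlignableError(ValueError):
    """Query does not align to the reference window (suspected non-bovine/NUMT)."""


@dataclass(frozen=True)
class VariantProfile:
    """The mutations carried by one sample over its covered window."""

    sample_id: str
    breed: str
    covered: RegionWindow
    mutations: MutationSet

    def __post_init__(self) -> None:
        for m in self.mutations:
            if not position_in_window(m.position, self.covered):
                raise ValueError(
                    f"mutation {m.token()} outside covered window "
                    f"{self.covered.start_np}-{self.covered.end_np}"
                )

    def restricted_to(self, window: RegionWindow) -> "VariantProfile":
        """Profile with mutations filtered to ``window`` (coverage unchanged)."""
        kept = MutationSet(tuple(m for m in self.mutations
                                 if position_in_window(m.position, window)))
        return VariantProfile(self.sample_id, self.breed, self.covered, kept)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def apply_mutations(
    reference: ReferenceGenome, mutations: MutationSet, window: RegionWindow
) -> str:
    """Edit the reference window by a mutation set; inverse of call_variants.

    Transitions substitute the A<->G / C<->T partner of the reference base;
    transversions substitute the explicit derived base, which must differ
    from the reference base and must not be its transition partner.
    """
    positions = reference.window_positions(window)
    pos_index = {np_: i for i, np_ in enumerate(positions)}
    # per-position edit: (replacement bases for the position, trailing insert)
    subst: dict[int, str] = {}
    inserts: dict[int, str] = {}
    for m in mutations:
        if m.position not in pos_index:
            raise ValueError(f"mutation {m.token()} outside window")
        ref_base = reference.base_at(m.position)
        if m.kind == "transition":
            subst[m.position] = transition_partner(ref_base)
        elif m.kind == "transversion":
            if m.derived_base == ref_base:
                raise ValueError(
                    f"transversion {m.token()} equals reference base {ref_base}"
                )
            if m.derived_base == transition_partner(ref_base):
                raise ValueError(
                    f"{m.token()} is a transition of reference base {ref_base}, "
                    "not a transversion"
                )
            subst[m.position] = m.derived_base
        elif m.kind == "deletion":
            subst[m.position] = ""
        else:  # insertion after position
            inserts[m.position] = inserts.get(m.position, "") + m.inserted_seq
    out = []
    for np_ in positions:
        base = subst.get(np_, reference.base_at(np_))
        out.append(base)
        if np_ in inserts:
            out.append(inserts[np_])
    return "".join(out)


def call_variants(
    query: str,
    reference: ReferenceGenome,
    window: RegionWindow,
    sample_id: str = "query",
    breed: str = "Unknown",
    min_identity: float = 0.80,
) -> VariantProfile:
    """Align ``query`` to the reference window and emit its mutations.

    Global affine-gap alignment (match +1, mismatch -1, gap open -4,
    extend -1); every difference becomes a Mutation.  Ambiguous (N) query
    positions are excluded from calls.  Indels are right-shifted to their
    3'-most placement within repeats before being reported.
    """
    query = query.upper()
    ref_win = reference.window_sequence(window)
    positions = reference.window_positions(window)
    wlen = len(ref_win)
    if not 0.8 * wlen <= len(query) <= 1.2 * wlen:
        raise ValueError(
            f"query length {len(query)} outside +-20% of window length {wlen}"
        )
    unambiguous = sum(query.count(b) for b in "ACGT")
    if unambiguous < 0.9 * len(query):
        raise ValueError("query has more than 10% ambiguous bases")

    aligner = _make_aligner()
    aln = aligner.align(ref_win, query.replace("N", "A") if "N" in query else query)[0]
    gapped_ref, gapped_qry = str(aln[0]), str(aln[1])
    # restore Ns masked for alignment scoring
    if "N" in query:
        qi = 0
        chars = list(gapped_qry)
        for k, c in enumerate(chars):
            if c != "-":
                if query[qi] == "N":
                    chars[k] = "N"
                qi += 1
        gapped_qry = "".join(chars)

    matches = sum(
        1 for a, b in zip(gapped_ref, gapped_qry) if a == b and a != "-"
    )
    aligned_cols = sum(
        1 for a, b in zip(gapped_ref, gapped_qry) if a != "-" and b != "-"
    )
    if aligned_cols == 0 or matches / aligned_cols < min_identity:
        raise NotAlignableError(
            f"alignment identity below {min_identity:.0%} for sample {sample_id}"
        )

    substitutions: list[tuple[int, str]] = []  # (ref window index, derived base)
    deletions: list[int] = []  # ref window indices deleted
    insertions: list[tuple[int, str]] = []  # (after ref window index, bases)
    ri = -1  # last consumed ref index
    for a, b in zip(gapped_ref, gapped_qry):
        if a != "-":
            ri += 1
        if a == "-":
            if b == "N":
                continue
            insertions.append((ri, b))
        elif b == "-":
            deletions.append(ri)
        elif a != b:
            if b == "N":
                continue
            substitutions.append((ri, b))
    # merge consecutive inserted bases at the same anchor
    merged_ins: list[tuple[int, str]] = []
    for anchor, base in insertions:
        if merged_ins and merged_ins[-1][0] == anchor:
            merged_ins[-1] = (anchor, merged_ins[-1][1] + base)
        else:
            merged_ins.append((anchor, base))

    muts: list[Mutation] = []
    for idx, derived in substitutions:
        ref_base = ref_win[idx]
        if derived == transition_partner(ref_base):
            muts.append(Mutation(positions[idx], "transition"))
        else:
            muts.append(Mutation(positions[idx], "transversion", derived_base=derived))
    # group deleted indices into blocks, then shift each block 3'-most as a
    # unit (deleting [s, e] equals deleting [s+1, e+1] iff ref[s] == ref[e+1])
    blocks: list[list[int]] = []
    for idx in deletions:
        if blocks and idx == blocks[-1][-1] + 1:
            blocks[-1].append(idx)
        else:
            blocks.append([idx])
    for block in blocks:
        s, e = block[0], block[-1]
        while e + 1 < wlen and ref_win[s] == ref_win[e + 1]:
            s += 1
            e += 1
        for k in range(s, e + 1):
            muts.append(Mutation(positions[k], "deletion"))
    for anchor, bases in merged_ins:
        a, s = anchor, bases
        while a + 1 < wlen and ref_win[a + 1] == s[0]:
            s = s[1:] + s[0]
            a += 1
        if a < 0:
            # insertion before the window start anchors to the last position
            # of the preceding (uncovered) frame; report at the first np
            a = 0
        muts.append(Mutation(positions[a], "insertion", inserted_seq=s))

    return VariantProfile(sample_id, breed, window, MutationSet(tuple(muts)))
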