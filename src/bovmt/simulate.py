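"""Synthetic data generation: reference stand-in, breed panels, clades.

Everything the pipeline consumes can be generated here, seeded and
deterministic: a synthetic reference genome on the real coordinate frame,
control-region panels in which each sample carries a haplogroup motif plus
Poisson-distributed private mutations, and clock-evolved clades with a known
TMRCA for calibrating the dating statistics.

The default generator settings mirror the study conditions this package is
tested against: a 16,338-bp circular genome, the control-region read window
np 15823-215, a private-mutation mean of 1.5 per control-region sequence,
and the coding-region clock of one substitution per 3,172 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dating import RateModel
from .haplogroups import HaplogroupDefinition, default_definitions
from .mutation import Mutation, MutationSet
from .parsimony import CladeTree, TreeNode
from .reference import (
    BRS_LENGTH,
    CONTROL_WINDOW,
    ReferenceGenome,
    RegionWindow,
    position_in_window,
)
from .variants import VariantProfile, apply_mutations

__all__ = [
    "synthetic_reference",
    "PanelSpec",
    "CladeSpec",
    "generate_panel",
    "simulate_clade",
    "star_clade_tree",
]

_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "T")


def synthetic_reference(
    length: int = BRS_LENGTH,
    seed: int = 2011,
    definitions: Sequence[HaplogroupDefinition] | None = None,
    id: str = "BRS-synthetic",
) -> ReferenceGenome:
    """Deterministic synthetic stand-in for the bovine reference sequence.

    This is not the real GenBank V00654 sequence; it is a seeded random
    genome of the same length on the same coordinate frame, with bases at
    motif positions constrained so that every motif token is applicable:
    a transversion site gets a reference base of the opposite purine/
    pyrimidine class, and the base following an insertion site differs from
    the first inserted base so that the insertion is already at its 3'-most
    placement.  All downstream arithmetic (motif matching, parsimony
    counts, rho/sigma) depends only on the coordinate frame, never on the
    actual reference bases.
    """
    if definitions is None:
        definitions = default_definitions()
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))
    motif_muts = [m for d in definitions for m in d.motif]
    for m in motif_muts:
        if m.position > length:
            raise ValueError(
                f"motif position {m.position} exceeds synthetic length {length}"
            )
        if m.kind == "transversion":
            pool = _PYRIMIDINES if m.derived_base in _PURINES else _PURINES
            seq[m.position - 1] = pool[rng.integers(0, 2)]
        elif m.kind == "insertion":
            nxt = m.position % length  # 0-based index of the following np
            if seq[nxt] == m.inserted_seq[0]:
                others = [b for b in "ACGT" if b != m.inserted_seq[0]]
                seq[nxt] = others[rng.integers(0, 3)]
        elif m.kind == "deletion":
            nxt = m.position % length
            if seq[nxt] == seq[m.position - 1]:
                others = [b for b in "ACGT" if b != seq[m.position - 1]]
                seq[nxt] = others[rng.integers(0, 3)]
    return ReferenceGenome(id=id, sequence="".join(seq))


@dataclass(frozen=True)
class PanelSpec:
    """A breed panel: per-breed haplogroup counts plus a private-mutation rate.

    ``counts`` maps breed -> {haplogroup name -> number of samples}.  Each
    sample receives its haplogroup motif plus Poisson(``lambda_private``)
    private transitions at non-diagnostic window positions.
    """

    counts: Mapping[str, Mapping[str, int]]
    lambda_private: float = 1.5
    seed: int = 0
    window: RegionWindow = CONTROL_WINDOW
    #: allow private mutations at diagnostic motif sites (classifier stress)
    confusable: bool = False

    def __post_init__(self) -> None:
        for breed, haps in self.counts.items():
            for hap, n in haps.items():
                if n < 0:
                    raise ValueError(f"negative count for {breed}/{hap}")

    @classmethod
    def from_frequencies(
        cls,
        breed_sizes: Mapping[str, int],
        frequencies: Mapping[str, Mapping[str, float]],
        **kwargs,
    ) -> "PanelSpec":
        """Build integer counts from per-breed percentage targets.

        Percentages must sum to <= 100 per breed; the remainder is T3.
        Non-integral targets are rounded down with the shortfall going to
        T3 (a warning is impossible to act on in batch use, so the achieved
        counts are simply what the spec records).
        """
        counts: dict[str, dict[str, int]] = {}
        for breed, n in breed_sizes.items():
            freqs = frequencies.get(breed, {})
            if sum(freqs.values()) > 100.0 + 1e-9:
                raise ValueError(f"frequencies for {breed} exceed 100%")
            c = {h: int(n * f / 100.0) for h, f in freqs.items() if f > 0}
            assigned = sum(c.values())
            c["T3"] = c.get("T3", 0) + (n - assigned)
            counts[breed] = c
        return cls(counts=counts, **kwargs)


def generate_panel(
    spec: PanelSpec,
    reference: ReferenceGenome | None = None,
    definitions: Sequence[HaplogroupDefinition] | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate (sample_id, sequence) records and a metadata table.

    Deterministic under ``spec.seed``: identical specs yield identical
    sequences.  Metadata columns: sample_id, breed, start_np, end_np,
    true_haplogroup.
    """
    if definitions is None:
        definitions = default_definitions()
    if reference is None:
        reference = synthetic_reference(definitions=definitions)
    by_name = {d.name: d for d in definitions}
    rng = np.random.default_rng(spec.seed)

    window_positions = reference.window_positions(spec.window)
    diagnostic = {m.position for d in definitions for m in d.motif}
    if spec.confusable:
        private_pool = np.array(window_positions)
    else:
        private_pool = np.array([p for p in window_positions if p not in diagnostic])

    records: list[tuple[str, str]] = []
    meta_rows = []
    i = 0
    for breed in sorted(spec.counts):
        for hap in sorted(spec.counts[breed]):
            if hap not in by_name:
                raise ValueError(f"unknown haplogroup {hap!r} in panel spec")
            # a read only shows the motif sites its window covers
            motif = MutationSet(
                tuple(
                    m for m in by_name[hap].motif
                    if position_in_window(m.position, spec.window)
                )
            )
            for _ in range(spec.counts[breed][hap]):
                i += 1
                sample_id = f"S{i:05d}"
                k = rng.poisson(spec.lambda_private)
                k = min(k, len(private_pool))
                priv_pos = rng.choice(private_pool, size=k, replace=False)
                taken = motif.positions
                private = MutationSet(
                    tuple(
                        Mutation(int(p), "transition")
                        for p in priv_pos
                        if int(p) not in taken
                    )
                )
                muts = motif.union(private)
                seq = apply_mutations(reference, muts, spec.window)
                records.append((sample_id, seq))
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "breed": breed,
                        "start_np": spec.window.start_np,
                        "end_np": spec.window.end_np,
                        "true_haplogroup": hap,
                    }
                )
    if not records:
        raise ValueError("panel spec produced no samples")
    return records, pd.DataFrame(meta_rows)


@dataclass(frozen=True)
class CladeSpec:
    """A clock-evolved clade with known TMRCA.

    ``genealogy`` is ``"star"`` (all tips attach directly to the root; the
    closed forms for rho and sigma hold exactly) or ``"coalescent"``
    (standard n-coalescent internode times rescaled so the root sits at
    exactly ``tmrca_years``).  ``tip_ages_years`` foreshortens ancient
    tips' terminal branches.
    """

    n_tips: int
    tmrca_years: float
    genealogy: str = "star"
    tip_ages_years: tuple[float, ...] = ()
    rates: RateModel = field(default_factory=RateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("a clade needs at least two tips")
        if self.genealogy not in ("star", "coalescent"):
            raise ValueError(f"unknown genealogy {self.genealogy!r}")
        ages = self.tip_ages_years or (0.0,) * self.n_tips
        if len(ages) != self.n_tips:
            raise ValueError("one tip age per tip required")
        if any(a < 0 for a in ages):
            raise ValueError("tip ages must be non-negative")
        if self.tmrca_years < 0:
            raise ValueError("TMRCA must be non-negative")
        if max(ages) > 0 and self.tmrca_years <= max(ages):
            raise ValueError("TMRCA must exceed the oldest tip age")

    @property
    def ages(self) -> tuple[float, ...]:
        return self.tip_ages_years or (0.0,) * self.n_tips


def _coalescent_node_times(n: int, rng: np.random.Generator) -> np.ndarray:
    """Coalescence times (most recent first), rescaled later to the TMRCA."""
    times = []
    t = 0.0
    for k in range(n, 1, -1):
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        times.append(t)
    return np.asarray(times)


def simulate_clade(
    spec: CladeSpec, window: RegionWindow | None = None
) -> list[VariantProfile]:
    """Profiles of one simulated clade; the root haplotype is the reference.

    Mutations are Poisson with mean branch_years / years_per_substitution,
    placed at uniformly drawn, globally non-repeating coding-window
    positions as transitions, so every mutation is unique and the true
    root state is the empty set.
    """
    window = window or spec.rates.coding_window
    rng = np.random.default_rng(spec.seed)
    rate = 1.0 / spec.rates.years_per_substitution
    n = spec.n_tips
    ages = spec.ages

    # branch lengths in years from each tip up to the root, per lineage,
    # expressed as a list of branch segments shared by sets of tips
    segments: list[tuple[float, frozenset[int]]] = []
    if spec.genealogy == "star":
        for i in range(n):
            segments.append((spec.tmrca_years - ages[i], frozenset({i})))
    else:
        raw = _coalescent_node_times(n, rng)
        node_times = raw * (spec.tmrca_years / raw[-1])
        # Kingman topology: merge two uniformly chosen lineages per event
        lineages: list[tuple[frozenset[int], float]] = [
            (frozenset({i}), ages[i]) for i in range(n)
        ]
        for t in node_times:
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            (set_i, t_i), (set_j, t_j) = lineages[i], lineages[j]
            segments.append((max(t - t_i, 0.0), set_i))
            segments.append((max(t - t_j, 0.0), set_j))
            merged = (set_i | set_j, t)
            lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
            lineages.append(merged)

    # a window position can host at most one mutation across the clade;
    # positions are drawn uniformly with rejection against prior draws
    if window.wraps:
        raise ValueError("clade simulation expects a non-wrapping coding window")
    wsize = window.end_np - window.start_np + 1
    used: set[int] = set()

    tip_mutations: dict[int, list[Mutation]] = {i: [] for i in range(n)}
    for years, members in segments:
        k = rng.poisson(years * rate)
        if len(used) + k > wsize:
            raise ValueError("mutation count exceeds window size")
        for _ in range(k):
            while True:
                pos = int(rng.integers(window.start_np, window.end_np + 1))
                if pos not in used:
                    used.add(pos)
                    break
            m = Mutation(pos, "transition")
            for i in members:
                tip_mutations[i].append(m)

    return [
        VariantProfile(
            sample_id=f"tip{i:03d}",
            breed="simulated",
            covered=window,
            mutations=MutationSet(tuple(tip_mutations[i])),
        )
        for i in range(n)
    ]


def star_clade_tree(
    profiles: Sequence[VariantProfile], name: str = "star"
) -> CladeTree:
    """Rooted star tree with the reference haplotype at the root.

    For clades generated under a star genealogy the topology is known, so
    the tree is constructed directly rather than searched for.
    """
    root = TreeNode(state=MutationSet())
    for p in profiles:
        root.children.append(
            TreeNode(
                state=p.mutations,
                branch=p.mutations,
                branch_length=float(len(p.mutations)),
                label=p.sample_id,
                samples=(p.sample_id,),
            )
        )
    tree = CladeTree(root, name, rooted=True)
    tree.validate()
    return tree
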