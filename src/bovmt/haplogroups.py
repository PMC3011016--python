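"""Motif-based haplogroup classification of bovine mtDNA profiles.

Taurine haplogroups are defined by control-region mutational motifs relative
to the reference (BRS): the common haplogroup T3 is the reference haplotype
itself, T1/T2/T4/T5 and the macro-haplogroup T1'2'3 carry short motifs, and
the rare non-T haplogroups P, Q and R carry longer ones (27 sites for R).
Classification scores each motif over the sites a sample's read window
actually covers; short sequences that miss a diagnostic site (classically np
15953, which separates Q from T1'2'3) yield an explicit ambiguity set
rather than a forced call.

Site 169 is mutationally unstable and scores at half weight, so its absence
never blocks a motif match on its own.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mutation import MutationSet, parse_motif
from .reference import position_in_window
from .variants import VariantProfile

__all__ = [
    "HaplogroupDefinition",
    "ClassificationResult",
    "UninformativeCoverageError",
    "default_definitions",
    "load_definitions",
    "classify",
    "survey",
    "DEFAULT_MOTIFS",
]

#: Control-region motifs exactly as established for taurine cattle.
#: T3 is the reference haplotype (empty motif).  P and R tolerate a partial
#: match (>= 80% of covered motif weight) because single sites of a long
#: motif are occasionally lost to recurrent mutation.
DEFAULT_MOTIFS: dict[str, dict] = {
    "T1'2'3": {"motif": "169-16255", "parent": None},
    "T1": {"motif": "169-16113-16255", "parent": "T1'2'3"},
    "T2": {"motif": "169-16057C-16185-16255", "parent": "T1'2'3"},
    "T3": {"motif": "", "parent": "T1'2'3"},
    "T4": {"motif": "169-16042-16093-16302", "parent": "T3"},
    "T5": {"motif": "163-169-16255", "parent": None},
    "Q": {"motif": "169-15953G-16255", "parent": None},
    "P": {
        "motif": "106-166-190-221+C-222-249-300-301-15951-15953G-15994-16049-"
                 "16051-16058-16074-16085-16122-16231-16255-16264",
        "parent": None,
        "min_match": 0.8,
    },
    "R": {
        "motif": "8-106-166-221+C-234+T-249-296-300-15818-15900-15951-15953G-"
                 "16057-16076-16084-16085-16121-16122-16127-16135-16137-"
                 "16200+A-16231-16248-16250-16264-16301",
        "parent": None,
        "min_match": 0.8,
    },
}

#: Canonical column order for survey tables.
SURVEY_ORDER = ["T1'2'3", "T1", "T2", "T3", "T4", "T5", "Q", "R"]


class UninformativeCoverageError(ValueError):
    """The profile's window covers no diagnostic site of any motif."""


@dataclass(frozen=True)
class HaplogroupDefinition:
    """A named motif: the classifier's rulebook entry."""

    name: str
    motif: MutationSet
    parent: str | None = None
    #: minimum weighted fraction of covered motif sites that must be present
    min_match: float = 1.0

    @classmethod
    def from_motif_string(cls, name: str, motif: str, parent: str | None = None,
                          min_match: float = 1.0) -> "HaplogroupDefinition":
        return cls(name=name, motif=parse_motif(motif), parent=parent,
                   min_match=min_match)


def default_definitions() -> list[HaplogroupDefinition]:
    return [
        HaplogroupDefinition.from_motif_string(
            name, spec["motif"], spec.get("parent"), spec.get("min_match", 1.0)
        )
        for name, spec in DEFAULT_MOTIFS.items()
    ]


def load_definitions(path) -> list[HaplogroupDefinition]:
    """Load a motif table from JSON: {name: motif string | {motif, parent, min_match}}."""
    with open(path) as fh:
        raw = json.load(fh)
    defs = []
    for name, spec in raw.items():
        if isinstance(spec, str):
            spec = {"motif": spec}
        defs.append(
            HaplogroupDefinition.from_motif_string(
                name, spec["motif"], spec.get("parent"), spec.get("min_match", 1.0)
            )
        )
    return defs


@dataclass(frozen=True)
class ClassificationResult:
    sample_id: str
    #: single haplogroup name, or tuple of names when the call is ambiguous
    call: str | tuple[str, ...]
    matched: MutationSet
    missing_diagnostics: tuple[int, ...]
    private_mutations: MutationSet
    full_match: bool
    scores: Mapping[str, float] = field(default_factory=dict)

    @property
    def is_ambiguous(self) -> bool:
        return isinstance(self.call, tuple)

    @property
    def call_label(self) -> str:
        if self.is_ambiguous:
            return "/".join(self.call)
        return self.call


def _evaluate(profile: VariantProfile, definition: HaplogroupDefinition):
    """Coverage-restricted motif evaluation for one haplogroup."""
    covered = [m for m in definition.motif
               if position_in_window(m.position, profile.covered)]
    present = [m for m in covered if m in profile.mutations]
    uncovered = [m for m in definition.motif if m not in MutationSet(tuple(covered))]
    w_cov = sum(m.weight for m in covered)
    w_pres = sum(m.weight for m in present)
    score = w_pres / w_cov if w_cov > 0 else 0.0
    stable_covered = [m for m in covered if m.weight == 1.0]
    stable_present = [m for m in present if m.weight == 1.0]
    if definition.min_match < 1.0:
        matches = w_cov > 0 and score >= definition.min_match
    else:
        # every covered stable site must be present; the unstable 169 cannot
        # block a match on its own
        matches = len(stable_covered) == len(stable_present)
    return {
        "covered": covered,
        "present": present,
        "uncovered": uncovered,
        "score": score,
        "matches": matches,
        "full": len(present) == len(definition.motif),
    }


def classify(
    profile: VariantProfile, definitions: Sequence[HaplogroupDefinition] | None = None
) -> ClassificationResult:
    """Assign a profile to a haplogroup, or to an ambiguity set.

    The unique matching haplogroup with the largest motif wins ("most
    specific wins": nested motifs such as T1'2'3 within T1 resolve to the
    larger matched motif).  A competing matching haplogroup remains in the
    ambiguity set when every stable site that distinguishes the winner from
    it lies outside the covered window.  Profiles matching nothing beyond
    the reference are called T3.
    """
    if definitions is None:
        definitions = default_definitions()
    if not definitions:
        raise ValueError("no haplogroup definitions supplied")
    by_name = {d.name: d for d in definitions}

    evals = {d.name: _evaluate(profile, d) for d in definitions}
    informative = [n for n, e in evals.items() if e["covered"] or not by_name[n].motif]
    if all(not e["covered"] for n, e in evals.items() if by_name[n].motif):
        raise UninformativeCoverageError(
            f"window of sample {profile.sample_id} covers no motif site"
        )

    candidates = [
        n for n in informative
        if evals[n]["matches"] and evals[n]["present"]
    ]
    if not candidates:
        fallback = next((d.name for d in definitions if not d.motif), None)
        if fallback is None:
            raise ValueError("no matching haplogroup and no reference fallback defined")
        return ClassificationResult(
            sample_id=profile.sample_id,
            call=fallback,
            matched=MutationSet(),
            missing_diagnostics=(),
            private_mutations=profile.mutations,
            full_match=True,
            scores={n: e["score"] for n, e in evals.items()},
        )

    max_size = max(len(by_name[n].motif) for n in candidates)
    winners = sorted(n for n in candidates if len(by_name[n].motif) == max_size)
    winner = winners[0]
    ambiguity = set(winners)

    for c in candidates:
        if c in ambiguity:
            continue
        distinguishing = [
            m for m in by_name[winner].motif
            if m.weight == 1.0 and m not in by_name[c].motif
        ]
        if distinguishing and all(
            not position_in_window(m.position, profile.covered)
            for m in distinguishing
        ):
            ambiguity.add(c)

    ev = evals[winner]
    matched = MutationSet(tuple(ev["present"]))
    # hard guarantee: a non-partial call never claims an absent covered
    # stable site
    if by_name[winner].min_match >= 1.0:
        assert all(
            m in profile.mutations for m in ev["covered"] if m.weight == 1.0
        ), "classifier assigned a haplogroup lacking a covered motif site"

    call: str | tuple[str, ...]
    call = winner if ambiguity == {winner} else tuple(sorted(ambiguity))
    return ClassificationResult(
        sample_id=profile.sample_id,
        call=call,
        matched=matched,
        missing_diagnostics=tuple(sorted(m.position for m in ev["uncovered"])),
        private_mutations=profile.mutations.difference(by_name[winner].motif),
        full_match=ev["full"],
        scores={n: e["score"] for n, e in evals.items()},
    )


def _round1(x: float) -> float:
    """Round half-up to one decimal (survey-table convention)."""
    return math.floor(x * 10 + 0.5) / 10


def survey(
    results: Iterable[ClassificationResult],
    breeds: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Breed x haplogroup frequency table (percent, one decimal).

    ``breeds`` maps sample_id to breed; samples without a breed fall into
    an "Unknown" bucket.  The table carries an N column and a Total row;
    ambiguous calls appear under a joined label (e.g. "Q/T1'2'3").
    """
    rows = []
    for r in results:
        breed = (breeds or {}).get(r.sample_id, "Unknown")
        rows.append({"sample_id": r.sample_id, "breed": breed, "call": r.call_label})
    if not rows:
        raise ValueError("survey requires at least one classification result")
    df = pd.DataFrame(rows)
    counts = df.pivot_table(index="breed", columns="call", aggfunc="size", fill_value=0)
    counts.loc["Total"] = counts.sum()
    n = counts.sum(axis=1)
    pct = counts.div(n, axis=0).mul(100.0).map(_round1)
    ordered = [c for c in SURVEY_ORDER if c in pct.columns] + sorted(
        c for c in pct.columns if c not in SURVEY_ORDER
    )
    out = pct[ordered]
    out.insert(0, "N", n.astype(int))
    return out
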