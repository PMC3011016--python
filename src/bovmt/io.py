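"""File formats, display conventions and the end-to-end pipeline.

Inputs are plain FASTA plus a CSV metadata table (sample_id, breed,
start_np, end_np); outputs are CSV tables (per-sample calls, a breed x
haplogroup survey, a haplotype listing) and, for complete-genome inputs,
a mutation-annotated newick tree with a dating table.

Haplotype strings in output tables follow the field's display convention
for the control region: positions from the window start up through the end
of the genome are listed first, then the wrapped positions after the
origin.  Storage everywhere else remains strictly ascending.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dating import RateModel
from .haplogroups import (
    ClassificationResult,
    HaplogroupDefinition,
    classify,
    default_definitions,
    load_definitions,
    survey,
)
from .mutation import MutationSet, parse_motif
from .reference import ReferenceGenome, RegionWindow, load_reference
from .variants import VariantProfile, call_variants

logger = logging.getLogger("bovmt")

__all__ = [
    "RunConfig",
    "display_tokens",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "profiles_table",
    "read_profiles_table",
    "run_pipeline",
]


def display_tokens(mutations: MutationSet, window: RegionWindow | None = None) -> str:
    """Motif string in display order (wrap order for wrapping windows)."""
    muts = list(mutations)
    if window is not None and window.wraps:
        muts.sort(key=lambda m: (m.position < window.start_np, m.position))
    return "-".join(m.token() for m in muts)


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "breed": str})
    required = {"sample_id", "breed", "start_np", "end_np"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    return df


def profiles_table(profiles: Sequence[VariantProfile]) -> pd.DataFrame:
    """Table S1-style haplotype listing: sample, breed, mutation string."""
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "breed": [p.breed for p in profiles],
            "mutations": [display_tokens(p.mutations, p.covered) for p in profiles],
        }
    )


def read_profiles_table(path, window: RegionWindow) -> list[VariantProfile]:
    """Re-parse a haplotype table written by :func:`profiles_table`."""
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            VariantProfile(
                sample_id=row["sample_id"],
                breed=row["breed"] or "Unknown",
                covered=window,
                mutations=parse_motif(row["mutations"]),
            )
        )
    return out


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for a pipeline run."""

    reference: ReferenceGenome
    definitions: tuple[HaplogroupDefinition, ...]
    window: RegionWindow
    rates: RateModel
    out_dir: Path
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        ref = load_reference(raw["reference"])
        defs = (
            tuple(load_definitions(raw["motifs"]))
            if "motifs" in raw
            else tuple(default_definitions())
        )
        w = raw.get("window", {})
        window = RegionWindow(w.get("start_np", 15823), w.get("end_np", 215))
        window.validate(ref.length)
        r = raw.get("rates", {})
        rates = RateModel(**r) if r else RateModel()
        return cls(
            reference=ref,
            definitions=defs,
            window=window,
            rates=rates,
            out_dir=Path(raw.get("out_dir", ".")),
            seed=int(raw.get("seed", 0)),
        )


def _calls_table(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "call": [r.call_label for r in results],
            "ambiguous": [r.is_ambiguous for r in results],
            "full_match": [r.full_match for r in results],
            "matched": [r.matched.motif_string() for r in results],
            "missing_diagnostics": [
                ";".join(str(p) for p in r.missing_diagnostics) for r in results
            ],
            "private_mutations": [r.private_mutations.motif_string() for r in results],
        }
    )


def run_pipeline(
    config: RunConfig,
    records: Sequence[tuple[str, str]],
    metadata: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Classify a panel end to end and write the output tables.

    Per-sample failures (unalignable sequences, uninformative coverage) are
    isolated: the failing sample is recorded with an ``error`` call and the
    batch continues.  Outputs: calls.csv, survey.csv, haplotypes.csv.
    """
    if not records:
        raise ValueError("no input sequences")
    meta = metadata.set_index("sample_id")
    config.out_dir.mkdir(parents=True, exist_ok=True)

    profiles: list[VariantProfile] = []
    results: list[ClassificationResult] = []
    errors: list[tuple[str, str]] = []
    for sample_id, seq in records:
        try:
            row = meta.loc[sample_id]
            window = RegionWindow(int(row["start_np"]), int(row["end_np"]))
            profile = call_variants(
                seq, config.reference, window,
                sample_id=sample_id, breed=str(row["breed"]),
            )
            result = classify(profile, list(config.definitions))
        except KeyError:
            logger.info("sample=%s stage=metadata decision=skip reason=no-metadata",
                        sample_id)
            errors.append((sample_id, "missing metadata"))
            continue
        except Exception as exc:  # noqa: BLE001 - isolate per-sample failures
            logger.info("sample=%s stage=classify decision=skip reason=%s",
                        sample_id, exc)
            errors.append((sample_id, str(exc)))
            continue
        profiles.append(profile)
        results.append(result)
        logger.info("sample=%s stage=classify decision=%s", sample_id,
                    result.call_label)
    if not results:
        raise ValueError("every sample failed; nothing to report")

    breeds = {p.sample_id: p.breed for p in profiles}
    calls = _calls_table(results)
    if errors:
        calls = pd.concat(
            [calls, pd.DataFrame(
                {"sample_id": [e[0] for e in errors],
                 "call": ["error: " + e[1] for e in errors]}
            )],
            ignore_index=True,
        )
    freq = survey(results, breeds)
    haplos = profiles_table(profiles)

    calls.to_csv(config.out_dir / "calls.csv", index=False)
    freq.to_csv(config.out_dir / "survey.csv")
    haplos.to_csv(config.out_dir / "haplotypes.csv", index=False)
    return {"calls": calls, "survey": freq, "haplotypes": haplos}
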