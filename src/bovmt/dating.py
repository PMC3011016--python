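"""Coalescence-time estimation: rho statistic, heuristic SE, ML distances.

The rho statistic is the average number of substitutions separating the
haplotypes of a clade from the clade's root haplotype; under a molecular
clock it converts to a time through the per-substitution rate.  Its
companion heuristic standard error is sigma = sqrt(sum over mutations of
n_m^2)/n, where n_m is the number of sampled tips descending through the
branch carrying mutation m and n the clade's sample count.  Both are
computed over the coding-region window (np 364-15791, 15,428 bp), for which
the calibrated clock is one substitution per 3,172 years (equivalently
2.043e-8 substitutions per site per year).

Clades containing radiocarbon-dated ancient specimens underestimate their
coalescence time because those lineages stop accumulating mutations at the
specimen's death; the mean tip age is added back as a correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .parsimony import CladeTree, TreeNode
from .reference import CODING_WINDOW, RegionWindow, position_in_window

__all__ = [
    "RateModel",
    "RhoEstimate",
    "rho",
    "sigma",
    "rho_estimate",
    "time_from_rho",
    "ml_distance",
    "tn93_distance",
    "combine_subclades",
    "adjust_for_ancient_tips",
    "round_half_up",
]

_SUBSTITUTIONS = ("transition", "transversion")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up rounding, the convention of the printed divergence tables."""
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class RateModel:
    """Calibrated bovine mtDNA coding-region clock."""

    years_per_substitution: float = 3172.0
    subs_per_site_per_year: float = 2.043e-8
    subs_rate_se: float = 0.099e-8
    coding_window: RegionWindow = CODING_WINDOW
    coding_length: int = 15428

    def __post_init__(self) -> None:
        implied = 1.0 / (self.years_per_substitution * self.coding_length)
        if abs(implied - self.subs_per_site_per_year) / self.subs_per_site_per_year > 0.005:
            raise ValueError(
                "per-substitution and per-site rates disagree by more than 0.5%"
            )


@dataclass(frozen=True)
class RhoEstimate:
    """rho and its heuristic SE for one clade, with clock-converted times."""

    clade: str
    n_tips: int
    rho: float
    sigma: float
    t_years: float
    dt_years: float

    @property
    def t_ky(self) -> float:
        return round_half_up(self.t_years / 1000.0)

    @property
    def dt_ky(self) -> float:
        return round_half_up(self.dt_years / 1000.0)


def _branch_contributions(
    clade: CladeTree, window: RegionWindow | None
) -> list[tuple[int, int]]:
    """(substitution count, subtended tip multiplicity) per branch."""
    if not getattr(clade, "rooted", True):
        raise ValueError("rho requires a rooted clade tree")

    out: list[tuple[int, int]] = []

    def walk(node: TreeNode) -> int:
        below = node.multiplicity
        for c in node.children:
            below += walk(c)
        if node is not clade.root:
            muts = [
                m for m in node.branch
                if m.kind in _SUBSTITUTIONS
                and (window is None or position_in_window(m.position, window))
            ]
            if muts:
                out.append((len(muts), below))
        return below

    walk(clade.root)
    return out


def rho(clade: CladeTree, window: RegionWindow | None = None) -> float:
    """Mean number of window substitutions from the root across sampled tips.

    Computed by the per-mutation identity rho = (sum over mutations m of
    n_m)/n, which equals the mean root-to-tip substitution count.
    """
    n = clade.n_samples
    if n == 0:
        raise ValueError("clade has no sampled tips")
    return sum(k * n_m for k, n_m in _branch_contributions(clade, window)) / n


def sigma(clade: CladeTree, window: RegionWindow | None = None) -> float:
    """Heuristic SE of rho: sqrt(sum over mutations of n_m^2)/n."""
    n = clade.n_samples
    if n == 0:
        raise ValueError("clade has no sampled tips")
    return math.sqrt(sum(k * n_m**2 for k, n_m in _branch_contributions(clade, window))) / n


def time_from_rho(
    rho_value: float, sigma_value: float, rates: RateModel | None = None
) -> tuple[float, float]:
    """Clock conversion to (T, dT) in ky, rounded half-up to 0.1."""
    if rho_value < 0 or sigma_value < 0:
        raise ValueError("rho and sigma must be non-negative")
    rates = rates or RateModel()
    t = rho_value * rates.years_per_substitution / 1000.0
    dt = sigma_value * rates.years_per_substitution / 1000.0
    return round_half_up(t), round_half_up(dt)


def rho_estimate(
    clade: CladeTree,
    window: RegionWindow | None = None,
    rates: RateModel | None = None,
    name: str | None = None,
) -> RhoEstimate:
    """Full rho/sigma/time summary for one rooted clade."""
    rates = rates or RateModel()
    r = rho(clade, window)
    s = sigma(clade, window)
    return RhoEstimate(
        clade=name or clade.name,
        n_tips=clade.n_samples,
        rho=r,
        sigma=s,
        t_years=r * rates.years_per_substitution,
        dt_years=s * rates.years_per_substitution,
    )


# ---------------------------------------------------------------------------
# ML distances (Tamura-Nei closed form with empirical base frequencies)

def _clean_columns(seqs: Sequence[str]) -> list[str]:
    """Complete deletion of gapped/ambiguous columns across all sequences."""
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must be aligned (equal length)")
    keep = [
        i for i in range(length)
        if all(s[i] in "ACGT" for s in seqs)
    ]
    if length and len(keep) < 0.5 * length:
        raise ValueError("fewer than 50% of sites remain after removing "
                         "gapped/ambiguous positions")
    return ["".join(s[i] for i in keep) for s in seqs]


def tn93_distance(seq1: str, seq2: str) -> tuple[float, float]:
    """Tamura-Nei (1993) distance and its delta-method variance.

    Base frequencies are estimated empirically from both sequences.  Falls
    back to zero for identical sequences.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be of equal length")
    L = len(seq1)
    if L == 0:
        raise ValueError("empty sequences")
    pooled = seq1 + seq2
    g = {b: pooled.count(b) / (2 * L) for b in "ACGT"}
    gR, gY = g["A"] + g["G"], g["C"] + g["T"]
    p1 = sum(1 for a, b in zip(seq1, seq2) if {a, b} == {"A", "G"}) / L
    p2 = sum(1 for a, b in zip(seq1, seq2) if {a, b} == {"C", "T"}) / L
    q = sum(
        1 for a, b in zip(seq1, seq2)
        if a != b and {a, b} not in ({"A", "G"}, {"C", "T"})
    ) / L
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0, 0.0
    if min(g.values()) <= 0 or gR <= 0 or gY <= 0:
        # degenerate composition: Jukes-Cantor fallback
        p = p1 + p2 + q
        d = -0.75 * math.log(1 - 4 * p / 3)
        var = p * (1 - p) / (L * (1 - 4 * p / 3) ** 2)
        return d, var
    k1 = 2 * g["A"] * g["G"] / gR
    k2 = 2 * g["C"] * g["T"] / gY
    k3 = 2 * (gR * gY - g["A"] * g["G"] * gY / gR - g["C"] * g["T"] * gR / gY)
    w1 = 1 - p1 / k1 - q / (2 * gR)
    w2 = 1 - p2 / k2 - q / (2 * gY)
    w3 = 1 - q / (2 * gR * gY)
    if min(w1, w2, w3) <= 0:
        raise ValueError("sequences too divergent for the TN93 correction")
    d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    c1 = 1 / w1
    c2 = 1 / w2
    c3 = k1 / (2 * gR * w1) + k2 / (2 * gY * w2) + k3 / (2 * gR * gY * w3)
    var = (
        c1**2 * p1 + c2**2 * p2 + c3**2 * q - (c1 * p1 + c2 * p2 + c3 * q) ** 2
    ) / L
    return d, max(var, 0.0)


def ml_distance(
    tip_sequences: Sequence[str],
    root_sequence: str,
    rates: RateModel | None = None,
    model: str = "TN93",
) -> tuple[float, float]:
    """Mean tip-to-root divergence in substitutions per site, with SE.

    Gapped and ambiguous positions are eliminated across all sequences
    before distances are computed (complete deletion); an error is raised
    if fewer than half the sites survive.
    """
    if len(tip_sequences) < 1:
        raise ValueError("at least one tip sequence required")
    cleaned = _clean_columns([root_sequence, *tip_sequences])
    root, tips = cleaned[0], cleaned[1:]
    dists, variances = [], []
    for t in tips:
        if model.upper() == "TN93":
            d, v = tn93_distance(root, t)
        elif model.lower() in ("p", "p-distance"):
            L = len(root)
            p = sum(1 for a, b in zip(root, t) if a != b) / L
            d, v = p, p * (1 - p) / L
        else:
            raise ValueError(f"unknown distance model {model!r}")
        dists.append(d)
        variances.append(v)
    n = len(dists)
    mean_d = float(np.mean(dists))
    se = math.sqrt(sum(variances)) / n
    return mean_d, se


def ml_time(
    divergence: float, se: float, rates: RateModel | None = None
) -> tuple[float, float]:
    """Convert a subs/site divergence to (T, dT) in ky, rounded to 0.1."""
    rates = rates or RateModel()
    t = divergence / rates.subs_per_site_per_year / 1000.0
    dt = se / rates.subs_per_site_per_year / 1000.0
    return round_half_up(t), round_half_up(dt)


# ---------------------------------------------------------------------------
# subclade combination and ancient-tip correction

def combine_subclades(
    contributions: Sequence[tuple[float, RhoEstimate]],
    rates: RateModel | None = None,
    name: str = "parent",
) -> RhoEstimate:
    """Inverse-variance weighted rho for a parent node.

    Each contribution is (offset, subclade estimate), where ``offset`` is
    the number of substitutions on the path from the parent root down to the
    subclade root.  The offset mutations are carried by every tip of the
    subclade, so the heuristic SE of the offset-augmented contribution is
    sqrt(sigma_i^2 + offset_i); weights are the inverse squared SEs, with a
    floor of 0.5/n_i for zero-variance subclades.
    """
    if not contributions:
        raise ValueError("at least one subclade required")
    rates = rates or RateModel()
    weights, values = [], []
    n_total = 0
    for offset, est in contributions:
        if offset < 0:
            raise ValueError("offsets must be non-negative")
        aug_rho = est.rho + offset
        aug_sigma = math.sqrt(est.sigma**2 + offset)
        if aug_sigma == 0:
            aug_sigma = 0.5 / est.n_tips
        weights.append(1.0 / aug_sigma**2)
        values.append(aug_rho)
        n_total += est.n_tips
    wsum = sum(weights)
    parent_rho = sum(w * v for w, v in zip(weights, values)) / wsum
    parent_sigma = math.sqrt(1.0 / wsum)
    return RhoEstimate(
        clade=name,
        n_tips=n_total,
        rho=parent_rho,
        sigma=parent_sigma,
        t_years=parent_rho * rates.years_per_substitution,
        dt_years=parent_sigma * rates.years_per_substitution,
    )


def adjust_for_ancient_tips(
    estimate: RhoEstimate,
    tip_ages_years: Sequence[float],
    rates: RateModel | None = None,
) -> RhoEstimate:
    """Correct a clade's time estimate for radiocarbon-dated ancient tips.

    Each ancient tip's lineage stopped accumulating mutations at the
    specimen's death, so a mean-based estimator underestimates the clade age
    by the mean tip age (modern tips contribute age 0):
    T_adjusted = T + mean(tip_ages).
    """
    rates = rates or RateModel()
    ages = list(tip_ages_years)
    if not ages:
        raise ValueError("tip ages required (0 for modern samples)")
    if any(a < 0 for a in ages):
        raise ValueError("tip ages must be non-negative")
    if len(ages) != estimate.n_tips:
        raise ValueError(
            f"expected {estimate.n_tips} tip ages, got {len(ages)}"
        )
    mean_age = sum(ages) / len(ages)
    return replace(
        estimate,
        rho=estimate.rho + mean_age / rates.years_per_substitution,
        t_years=estimate.t_years + mean_age,
    )
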