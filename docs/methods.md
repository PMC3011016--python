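# Methods

## Coordinate frame and windows

All positions are 1-based nucleotide positions ("np") on the circular
16,338-bp Bovine Reference Sequence frame. Windows are closed intervals
that may wrap through the origin; the two named windows are the
control-region read window np 15823–215 (731 bp) and the coding-region
window np 364–15791 (15,428 bp), over which the molecular clock is
defined. Conversions to half-open 0-based indices are private to the
reference module, so no user-facing API ever mixes conventions. The
reference alphabet is strictly A/C/G/T; ambiguity codes are legal in
queries only.

Because the real reference sequence cannot be bundled, the package ships a
*synthetic* stand-in generator (`bovmt.simulate.synthetic_reference`): a
seeded random genome of the correct length on the same coordinate frame.
Bases at motif positions are constrained so every motif token is
applicable — a transversion site receives a reference base of the opposite
purine/pyrimidine class, and the base following an insertion site differs
from the first inserted base, so the insertion is already at its canonical
3′-most placement. Every quantity the package is validated on (motif
matching, parsimony scores, ρ/σ, survey percentages) is arithmetic on
mutation *counts and positions*, never on the actual reference bases, so
the stand-in is exchangeable with the real sequence for those purposes.
Analyses of real FASTA data should load the real reference via
`load_reference`.

## Mutation notation

Tokens follow the standard shorthand: bare digits are transitions (the
derived allele is the A↔G / C↔T partner of the reference base); an
explicit base suffix is a transversion; `+` introduces inserted bases
(anchored to the np *after* which they sit); `d` marks a single-position
deletion. `(h)` flags heteroplasmy; `@` and `β` prefixes are tree-display
decorations for recurrence and back mutation. Decorations and
heteroplasmy never enter a mutation's identity key
(position, kind, derived allele), because the classifier scores motif
*presence*, not allele fraction, and recurrence reconstruction is
root-dependent. Mutation sets are stored strictly ascending by position;
the control-region display convention (window-start positions first, then
the wrapped positions after the origin) is applied only when formatting
output tables.

## Variant calling

Queries are aligned globally to the reference window with affine gap
penalties (match +1, mismatch −1, gap open −4, extend −1, via Biopython's
`PairwiseAligner`). The scheme is a conventional choice; the operative
contract is that apply-then-call round-trips every motif and random
conflict-free mutation sets, which the test suite enforces. Alignment
identity below 80% raises a "not alignable" error (suspected non-bovine or
nuclear-insert input). Indels are normalised to their 3′-most equivalent
placement: insertion strings are rotated rightward while the following
reference base matches their first base, and deletion blocks are shifted
rightward while the run continues — the standard mtDNA nomenclature
convention; homopolymer length variants therefore always receive the same
token. Ambiguous (N) query positions are masked during alignment and
excluded from calls.

## Haplogroup classification

The rulebook is the set of published control-region motifs (T1, T2, T3 ≡
reference, T4, T5, T1′2′3, P, Q, R). Classification of a profile proceeds
over the sites its covered window actually contains:

- A haplogroup *matches* when every covered **stable** motif site is
  present. Site 169 is mutationally unstable and carries weight 0.5; its
  absence never vetoes a match on its own.
- P and R (20- and 27-site motifs) instead require ≥ 80% of the covered
  motif weight, because single sites of a long motif are occasionally
  lost to recurrent private mutation; a `full_match` flag distinguishes
  exact matches.
- Among matching haplogroups the largest motif wins ("most specific
  wins"), which resolves the nested motifs (T1′2′3 ⊂ T1/T2, {169,16255} ⊂
  Q) the way practitioners do: a 16255 carrier without 15953G is T1′2′3,
  not Q.
- A competing matching haplogroup stays in the **ambiguity set** iff every
  stable site distinguishing the winner from it lies outside the covered
  window. A short read carrying 16255 but not covering np 15953 is
  therefore reported as {Q, T1′2′3}, never forced to a single call; with
  full coverage the same evidence resolves.
- Profiles matching nothing beyond the reference are T3. A window
  covering no motif site of any definition is an "uninformative coverage"
  error rather than a call.

Survey tables report per-breed percentages rounded half-up to 0.1 with an
N column and a Total row; counts are recoverable exactly from the
percentages at the stated N.

## Parsimony trees

Complete-genome haplotypes in this system differ by a handful of
mutations, so the search is exact at the scale the method is used:
identical profiles collapse onto one tip with a multiplicity, all unrooted
binary topologies are enumerated for up to 7 distinct haplotypes (Fitch
score per segregating site), and a stepwise-insertion branch and bound
(the score of a partial tree lower-bounds any completion) is used beyond
that. Ties among equally parsimonious topologies break on the smallest
canonical newick of haplotype labels, making every build deterministic.

Ancestral states are assigned per site by an exact unit-cost dynamic
program (valid for polytomies, unlike textbook Fitch refinement), with
ties resolved toward the reference-like state at the root and toward the
parent state below it — a delayed-transformation convention that pushes
changes tipward. Each branch then carries the symmetric difference of its
endpoint states, so the node-state invariant (child = parent XOR branch)
holds by construction and is re-validated after every operation. A
haplotype equal to an inferred ancestral state becomes a sampled ancestor
on a zero-length branch.

Rooting: midpoint (root at half the largest tip-to-tip mutation distance,
splitting an edge if needed; the split edge's mutations are partitioned
deterministically and the two root branches carry fractional lengths) or
outgroup (root at the outgroup's attachment node, outgroup dropped by
default). When the outgroup haplotype coincides with a sampled ingroup
haplotype the root *is* that node — the sampled-ancestor case that arises
when rooting a subclade at its own founder haplotype. Recurrence
annotation flags mutations seen on more than one branch; a branch mutation
that removes a state present on the root-to-node path is flagged as a back
mutation.

## Divergence dating

The ρ statistic is computed in its per-mutation form ρ = (Σ_m n_m)/n over
the substitutions (indels excluded) in the analysis window, where n_m is
the number of sampled tips descending through the branch carrying m; this
equals the mean root-to-tip substitution count, an identity the tests
check on simulated trees. The heuristic standard error is
σ = √(Σ_m n_m²)/n. On a star genealogy with k private mutations per tip
these reduce to ρ = k, σ = √(k/n).

Clock: 3,172 years per substitution across the 15,428-bp coding window,
equivalently 2.043 ± 0.099 ×10⁻⁸ substitutions/site/year; the RateModel
refuses configurations in which the two forms disagree by more than 0.5%.
Times are reported in ky rounded half-up to 0.1 — the rounding used
throughout the printed tables, and the one under which every published
ρ→T row reproduces exactly.

Parent-node estimates combine subclades by inverse-variance weighting:
a subclade entering with offset o (substitutions from the parent root down
to the subclade root) contributes ρ_i + o with SE √(σ_i² + o), since the
offset mutations subtend all n_i subclade tips; weights are 1/SE², the
parent SE is (Σ weights)^−½, and zero-variance subclades receive a floor
SE of 0.5/n_i to keep weights finite. With equal SEs and equal subclade
sizes the combination equals the direct ρ over all tips, which is the
oracle the tests use; the weighting itself is a declared design choice, as
the exact published formula is not stated.

ML distances use the Tamura–Nei (1993) closed form with empirical base
frequencies and a delta-method variance, after complete deletion of
columns containing gaps or ambiguity codes (an error if fewer than half
the sites survive). At the divergences involved (≤ 0.003 subs/site) any
near-additive model collapses onto the p-distance; ρ-based values, which
are model-free and exactly reproducible, are the primary quantities and ML
times are checked against them to 15% on simulated clades.

Ancient-tip correction: a tip radiocarbon-dated to a years BP stopped
accumulating mutations a years ago, so a mean-based estimator
underestimates the clade age by the *mean* tip age (moderns count 0):
T_adj = T + mean(ages). The mean — not the maximum — is the unbiased
correction for a mean-based estimator, which the simulation tests confirm
on two-tip clades with one ancient member.

## Synthetic data

`generate_panel` emulates a control-region survey: each sample is the
reference window edited by its haplogroup motif (restricted to the sites
the window covers — a read cannot show sites outside its span) plus
Poisson-distributed private transitions (mean 1.5 per sequence, matching
the diversity of a typical control-region survey) at non-diagnostic
positions; a `confusable` flag lifts that exclusion to stress-test the
classifier. `simulate_clade` draws a star or standard n-coalescent
genealogy rescaled so the root sits at exactly the requested TMRCA, places
Poisson(branch-years/3,172) mutations at uniformly drawn, globally
non-repeating coding positions (so the infinite-sites assumption holds by
construction), and foreshortens ancient tips' terminal branches by their
age. Identical seeds give byte-identical output.

What the generator does **not** emulate — sequencing error, heteroplasmy,
length heteroplasmy in homopolymer stretches, recurrent mutation at
hypervariable sites, NUMT contamination, realistic breed structure —
bounds what passing tests show: they validate the arithmetic and the
decision rules under the model's own assumptions, not robustness to real
laboratory artefacts.

## Problem sizes used in the checks

The acceptance computations run at the scale the statistics are defined
on: the 8-tip R1 and 2-tip P clades exactly as described, and one full
1,747-sample panel for the survey percentages. The parameter-recovery
suite uses 16-tip star clades at TMRCA 2, 16, 50 and 143 ky, 500
replicates each, requiring the true value inside ±2σ in ≥ 90% of
replicates; the exhaustive parsimony oracle runs on 5-haplotype instances
against an independent Fitch implementation (dendropy) over every
topology.

## Known limitations

- Parsimony search beyond ~10 distinct haplotypes becomes expensive; the
  intended scale (≤ 29 genomes, few distinct haplotypes per clade) is well
  inside the exact regime.
- Sub-haplogroup assignment (Q1/Q1a/Q2, R1/R2) requires coding-region
  data and tree placement; it is deliberately not attempted from
  control-region motifs alone.
- Zebu (indicine) motifs are not in the rulebook; such input surfaces as
  "not alignable" or an uninformative call rather than a haplogroup.
- Multi-position deletions are represented as runs of single-position
  `d` tokens; no amino-acid or RNA annotation is performed.
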