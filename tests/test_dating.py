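"""rho/sigma statistics, clock conversion, ML distances, corrections."""

import math

import numpy as np
import pytest

from bovmt.dating import (
    RateModel,
    RhoEstimate,
    adjust_for_ancient_tips,
    combine_subclades,
    ml_distance,
    ml_time,
    rho,
    rho_estimate,
    sigma,
    time_from_rho,
    tn93_distance,
)
from bovmt.mutation import Mutation, MutationSet, transition_partner
from bovmt.parsimony import build_parsimony_tree, root_tree
from bovmt.reference import CODING_WINDOW
from bovmt.simulate import CladeSpec, simulate_clade, star_clade_tree
from bovmt.variants import VariantProfile

W = CODING_WINDOW


def prof(sample_id, tokens):
    return VariantProfile(sample_id, "x", W, MutationSet.from_tokens(tokens))


def r1_tree():
    profiles = [prof(f"rom{i}", []) for i in range(1, 6)]
    profiles += [prof("cin1", ["15579"]), prof("cin2", ["15579"]),
                 prof("age1", ["15579", "5146", "6850"])]
    anc = prof("anc", [])
    return root_tree(build_parsimony_tree(profiles + [anc]), "outgroup", outgroup=anc)


def test_r1_rho_and_sigma_worked_example():
    tree = r1_tree()
    assert rho(tree, W) == pytest.approx(0.625)
    assert round(sigma(tree, W), 3) == 0.415
    t, dt = time_from_rho(rho(tree, W), sigma(tree, W))
    assert (t, dt) == (2.0, 1.3)


def test_p_two_tip_midpoint_worked_example():
    tokens = [str(400 + 7 * i) for i in range(11)]
    tree = root_tree(build_parsimony_tree([prof("p1", []), prof("p2", tokens)]),
                     "midpoint")
    assert rho(tree, W) == pytest.approx(5.5)
    assert round(sigma(tree, W), 3) == 1.658
    assert time_from_rho(5.5, sigma(tree, W)) == (17.4, 5.3)


def test_q2_star_fixture():
    profiles = [prof(f"a{i}", []) for i in range(3)]
    profiles += [prof(f"b{i}", ["5000"]) for i in range(3)]
    anc = prof("anc", [])
    tree = root_tree(build_parsimony_tree(profiles + [anc]), "outgroup", outgroup=anc)
    assert rho(tree, W) == pytest.approx(0.5)
    assert sigma(tree, W) == pytest.approx(0.5)


def test_all_tips_identical_to_root():
    tree = star_clade_tree([prof(f"s{i}", []) for i in range(4)])
    assert rho(tree) == 0.0
    assert sigma(tree) == 0.0


@pytest.mark.parametrize(
    "r,s,expected",
    [
        (5.250, 1.284, (16.7, 4.1)),   # Q
        (42.590, 4.420, (135.1, 14.0)),  # RPQT
        (21.000, 3.559, (66.6, 11.3)),  # PQT
        (14.235, 3.079, (45.2, 9.8)),   # QT
        (5.900, 1.552, (18.7, 4.9)),    # Q1
        (2.250, 1.299, (7.1, 4.1)),     # Q1a
        (0.500, 0.500, (1.6, 1.6)),     # Q2
        (5.500, 1.658, (17.4, 5.3)),    # P
        (13.900, 3.084, (44.1, 9.8)),   # R
        (0.625, 0.415, (2.0, 1.3)),     # R1
        (0.0, 0.0, (0.0, 0.0)),
    ],
)
def test_clock_conversion_reproduces_divergence_table(r, s, expected):
    assert time_from_rho(r, s) == expected


def test_time_from_rho_rejects_negative():
    with pytest.raises(ValueError):
        time_from_rho(-1.0, 0.0)


def test_rate_model_internal_consistency():
    m = RateModel()
    assert 1.0 / (m.years_per_substitution * m.coding_length) == pytest.approx(
        m.subs_per_site_per_year, rel=5e-3
    )
    with pytest.raises(ValueError):
        RateModel(years_per_substitution=5000.0)


def test_rho_requires_rooted_tree():
    tree = build_parsimony_tree([prof("a", []), prof("b", ["5000"])])
    assert not tree.rooted
    with pytest.raises(ValueError):
        rho(tree, W)


@pytest.mark.parametrize("seed", range(6))
def test_rho_identity_per_mutation_equals_mean_root_to_tip(seed):
    """The per-mutation form sum(n_m)/n must equal the mean number of
    branch substitutions on root-to-tip paths, tip multiplicities included."""
    spec = CladeSpec(n_tips=6, tmrca_years=40000, genealogy="coalescent", seed=seed)
    profiles = simulate_clade(spec)
    anc = prof("anc", [])
    tree = root_tree(build_parsimony_tree(profiles + [anc]), "outgroup", outgroup=anc)

    total = 0.0
    count = 0

    def walk(node, depth):
        nonlocal total, count
        depth += len(node.branch)
        if node.samples:
            total += depth * node.multiplicity
            count += node.multiplicity
        for c in node.children:
            walk(c, depth)

    walk(tree.root, -len(tree.root.branch) if tree.root.branch else 0)
    assert rho(tree, W) == pytest.approx(total / count)


@pytest.mark.parametrize("n,k", [(4, 2), (8, 3), (5, 1)])
def test_star_tree_closed_form(n, k):
    """n tips with k private mutations each: rho = k, sigma = sqrt(k/n)."""
    profiles = []
    for i in range(n):
        tokens = [str(400 + 100 * i + j) for j in range(k)]
        profiles.append(prof(f"s{i}", tokens))
    tree = star_clade_tree(profiles)
    assert rho(tree) == pytest.approx(k)
    assert sigma(tree) == pytest.approx(math.sqrt(k / n))


# ---------------------------------------------------------------------------
# ML distances

def _mutate(seq, n_subs, rng):
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for i in pos:
        out[i] = transition_partner(out[i])
    return "".join(out)


def test_pairwise_distance_matches_p_distance_limit():
    """Eleven substitutions over 15,428 bp: any near-additive model must
    approach the p-distance at this divergence (~3.6e-4 subs/site)."""
    rng = np.random.default_rng(0)
    s1 = "".join(rng.choice(list("ACGT"), size=15428))
    s2 = _mutate(s1, 11, rng)
    d, se = ml_distance([s2], s1)
    assert d == pytest.approx(11 / 15428, rel=0.01)
    # midpoint divergence of the two-tip clade, as a time
    t, _ = ml_time(d / 2, se / 2)
    assert abs(t - 17.4) / 17.4 < 0.10


def test_identical_sequences_have_zero_distance():
    s = "ACGT" * 100
    assert ml_distance([s], s) == (0.0, 0.0)


def test_gapped_and_ambiguous_columns_removed():
    s1 = "ACGTACGTACGTACGTACGT"
    s2 = "ACGTACGTACNTACGTACGT"  # one ambiguous column, no real difference
    d, _ = ml_distance([s2], s1)
    assert d == 0.0
    with pytest.raises(ValueError, match="50%"):
        ml_distance(["N" * 20], s1)


@pytest.mark.parametrize("true_subs", [30, 100])
def test_simulated_pairs_recover_true_distance(true_subs):
    """TN93 estimates fall within 3 SE of the generating distance."""
    rng = np.random.default_rng(5)
    L = 15428
    base = "".join(rng.choice(list("ACGT"), size=L))
    hits = 0
    reps = 40
    for _ in range(reps):
        n = rng.poisson(true_subs)
        s2 = _mutate(base, n, rng)
        d, se = ml_distance([s2], base)
        se = max(se, 1e-9)
        if abs(d - true_subs / L) <= 3 * se + 3 * math.sqrt(true_subs) / L:
            hits += 1
    assert hits / reps >= 0.9


def test_clock_consistency_between_rho_and_ml_times():
    """rho-based and ML-based times agree within 15% on a simulated clade."""
    from bovmt.simulate import synthetic_reference
    from bovmt.variants import apply_mutations

    ref = synthetic_reference()
    spec = CladeSpec(n_tips=12, tmrca_years=50000, seed=9)
    profiles = simulate_clade(spec)
    tree = star_clade_tree(profiles)
    t_rho, _ = time_from_rho(rho(tree, W), sigma(tree, W))

    root_seq = ref.window_sequence(W)
    tip_seqs = [apply_mutations(ref, p.mutations, W) for p in profiles]
    d, se = ml_distance(tip_seqs, root_seq)
    t_ml, _ = ml_time(d, se)
    assert abs(t_ml - t_rho) / t_rho < 0.15


# ---------------------------------------------------------------------------
# subclade combination

def test_combine_single_subclade_identity():
    est = RhoEstimate("A", 4, 2.0, 0.5, 2.0 * 3172, 0.5 * 3172)
    combined = combine_subclades([(0.0, est)])
    assert combined.rho == pytest.approx(2.0)
    assert combined.sigma == pytest.approx(0.5)


def test_combine_symmetric_subclades():
    a = RhoEstimate("A", 4, 2.0, 0.5, 0, 0)
    b = RhoEstimate("B", 4, 2.0, 0.5, 0, 0)
    combined = combine_subclades([(0.0, a), (0.0, b)])
    assert combined.rho == pytest.approx(2.0)
    assert combined.n_tips == 8
    assert combined.sigma < 0.5  # pooling reduces the SE


def test_combine_equal_sigma_matches_direct_computation():
    """Three symmetric subclades: the weighted combination must equal the
    direct rho over all tips computed on the hand-built full tree."""
    from bovmt.parsimony import CladeTree, TreeNode

    subtree_estimates = []
    full_root = TreeNode(state=MutationSet())
    offset_tokens = {"A": ["1000"], "B": ["2000"], "C": ["3000"]}
    for idx, (name, off) in enumerate(offset_tokens.items()):
        offset_set = MutationSet.from_tokens(off)
        private = [
            MutationSet.from_tokens([str(4000 + 500 * idx + 7 * i)])
            for i in range(4)
        ]
        # subclade estimate relative to its own root (offset stripped)
        sub = star_clade_tree([
            VariantProfile(f"{name}{i}", "x", W, pm)
            for i, pm in enumerate(private)
        ])
        subtree_estimates.append(rho_estimate(sub, W, name=name))
        # graft the same subclade, offset included, onto the full tree
        inner = TreeNode(state=offset_set, branch=offset_set, branch_length=1.0)
        for i, pm in enumerate(private):
            state = offset_set.union(pm)
            inner.children.append(
                TreeNode(state=state, branch=pm, branch_length=float(len(pm)),
                         label=f"{name}{i}", samples=(f"{name}{i}",))
            )
        full_root.children.append(inner)
    combined = combine_subclades([(1.0, e) for e in subtree_estimates])

    full = CladeTree(full_root, "full")
    full.validate()
    assert combined.rho == pytest.approx(rho(full, W))


def test_zero_variance_subclade_gets_floor():
    a = RhoEstimate("A", 4, 0.0, 0.0, 0, 0)
    b = RhoEstimate("B", 4, 2.0, 0.7, 0, 0)
    combined = combine_subclades([(0.0, a), (0.0, b)])
    assert math.isfinite(combined.rho)
    assert combined.rho < 2.0  # the zero-variance clade dominates


# ---------------------------------------------------------------------------
# ancient-tip correction

def test_ancient_tip_correction_matches_reported_adjustment():
    """P clade at 17.4 ky with one tip dead 6,738 y BP moves to ~20 ky."""
    est = RhoEstimate("P", 2, 5.5, 1.658, 5.5 * 3172, 1.658 * 3172)
    adjusted = adjust_for_ancient_tips(est, [6738, 0])
    assert 19.0 <= adjusted.t_ky <= 21.0


def test_modern_tips_leave_estimate_unchanged():
    est = RhoEstimate("X", 3, 1.0, 0.5, 3172.0, 1586.0)
    adjusted = adjust_for_ancient_tips(est, [0, 0, 0])
    assert adjusted.t_years == est.t_years


def test_negative_ages_rejected():
    est = RhoEstimate("X", 2, 1.0, 0.5, 3172.0, 1586.0)
    with pytest.raises(ValueError):
        adjust_for_ancient_tips(est, [-1, 0])


def test_adjusted_estimator_unbiased_for_ancient_two_tip_clades():
    """Over replicates of a 2-tip clade with one ancient tip, the corrected
    midpoint estimate is centred on the true TMRCA."""
    tmrca, age = 17400.0, 6738.0
    rates = RateModel()
    estimates = []
    for seed in range(400):
        spec = CladeSpec(n_tips=2, tmrca_years=tmrca,
                         tip_ages_years=(age, 0.0), seed=seed)
        profiles = simulate_clade(spec)
        tree = star_clade_tree(profiles)
        est = rho_estimate(tree, W, rates)
        estimates.append(adjust_for_ancient_tips(est, [age, 0.0], rates).t_years)
    mean = float(np.mean(estimates))
    se = float(np.std(estimates) / math.sqrt(len(estimates)))
    assert abs(mean - tmrca) < 3 * se + 0.01 * tmrca


# ---------------------------------------------------------------------------
# parameter recovery under the calibrated clock

@pytest.mark.parametrize("tmrca_ky", [2, 16, 50, 143])
def test_tmrca_recovery_within_two_sigma(tmrca_ky):
    """Star clades simulated under the clock recover the true TMRCA within
    2 sigma in at least 90% of replicates."""
    rates = RateModel()
    n_reps = 500
    hits = 0
    for seed in range(n_reps):
        spec = CladeSpec(n_tips=16, tmrca_years=tmrca_ky * 1000.0,
                         seed=seed * 4 + tmrca_ky)
        tree = star_clade_tree(simulate_clade(spec))
        est = rho_estimate(tree, W, rates)
        if abs(est.t_years - tmrca_ky * 1000.0) <= 2 * max(est.dt_years, 1e-9):
            hits += 1
    assert hits / n_reps >= 0.9
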