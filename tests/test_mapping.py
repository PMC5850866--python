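"""Endpoint-conditioned counts/abilities and the mapping dN/dS estimator."""

import numpy as np
import pytest

import codonmap as cm
from codonmap.genetic_code import SubstitutionLabel as L
from codonmap.mapping import (
    NUCLEOTIDES_PER_CODON,
    aggregate_dnds,
    branch_dnds,
    expected_count_matrix,
    expected_reward_matrix,
    joint_endpoint_posteriors,
    map_tree,
)
from codonmap.phylo import CodonAlignment
from conftest import mc_conditional


@pytest.mark.parametrize("t", [0.05, 0.5, 2.0])
@pytest.mark.parametrize("label", list(L))
def test_spectral_matches_uniformization(uniform_model, t, label):
    A = expected_count_matrix(uniform_model, label, t)
    B = expected_count_matrix(uniform_model, label, t, method="uniformization")
    assert np.abs(A - B).max() <= 1e-8 * np.abs(A).max()
    r = cm.neutral_counterpart(uniform_model).ability_vector(label)
    Ar = expected_reward_matrix(uniform_model, r, t)
    Br = expected_reward_matrix(uniform_model, r, t, method="uniformization")
    assert np.abs(Ar - Br).max() <= 1e-8 * np.abs(Ar).max()


def test_small_t_limits(uniform_model, code):
    x = code.index["AAA"]
    y_syn = code.index["AAG"]
    t = 1e-7
    assert cm.conditional_expected_count(uniform_model, L.SYNONYMOUS, t, x, x) == (
        pytest.approx(0.0, abs=1e-6)
    )
    # one synonymous difference: the conditioned path made exactly that jump
    assert cm.conditional_expected_count(uniform_model, L.SYNONYMOUS, t, x, y_syn) == (
        pytest.approx(1.0, abs=1e-6)
    )
    assert cm.conditional_expected_count(
        uniform_model, L.NONSYNONYMOUS, t, x, y_syn
    ) == pytest.approx(0.0, abs=1e-6)


def test_small_t_ability_is_instantaneous(uniform_model, code):
    x = code.index["AAA"]
    m0 = cm.neutral_counterpart(uniform_model)
    t = 1e-7
    got = cm.conditional_expected_ability(uniform_model, m0, L.SYNONYMOUS, t, x, x)
    want = cm.instantaneous_ability(m0, x, L.SYNONYMOUS) * t
    assert got == pytest.approx(want, rel=1e-4)


def test_unreachable_endpoint_rejected(uniform_model):
    with pytest.raises(ValueError, match="unreachable"):
        cm.conditional_expected_count(uniform_model, L.SYNONYMOUS, 0.0, 0, 1)


def test_stationary_total_count_identity(uniform_model):
    # summed over labels and endpoint pairs weighted by pi_x: equals t
    for t in (0.3, 1.7):
        tot = sum(expected_count_matrix(uniform_model, lab, t) for lab in L)
        assert uniform_model.pi @ tot.sum(axis=1) == pytest.approx(t, abs=1e-10)
        # same conservation with the total-rate reward on the neutral model
        r = -np.diag(uniform_model.Q)
        rew = expected_reward_matrix(uniform_model, r, t)
        assert uniform_model.pi @ rew.sum(axis=1) == pytest.approx(t, abs=1e-10)


def test_counts_match_monte_carlo(uniform_model, code):
    """Endpoint-conditioned expectations agree with a rejection-sampling
    Gillespie oracle within 3 standard errors."""
    x = code.index["AAA"]
    t = 0.5
    mc = mc_conditional(uniform_model, x, t, n_paths=30_000, seed=5)
    m0 = cm.neutral_counterpart(uniform_model)
    checked = 0
    for y, stats in mc.items():
        if stats["n_accepted"] < 1000:
            continue
        pairs = [
            (stats["n_syn"], cm.conditional_expected_count(uniform_model, L.SYNONYMOUS, t, x, y)),
            (stats["n_non"], cm.conditional_expected_count(uniform_model, L.NONSYNONYMOUS, t, x, y)),
            (stats["r_syn"], cm.conditional_expected_ability(uniform_model, m0, L.SYNONYMOUS, t, x, y)),
            (stats["r_non"], cm.conditional_expected_ability(uniform_model, m0, L.NONSYNONYMOUS, t, x, y)),
        ]
        for (mean, se), exact in pairs:
            # small absolute cushion: reward functionals are nearly
            # path-constant on no-jump endpoints, making se degenerate
            assert abs(mean - exact) <= 3 * se + 1e-3
        checked += 1
    assert checked >= 2  # at least the diagonal and one substitution endpoint


def test_joint_posterior_observed_endpoints(gc_model, code):
    # zero-length branch to A pins the root to A's state; the posterior on
    # the B branch is then a point mass at (state(A), state(B))
    tree = cm.tree_from_newick("(A:0.0,B:0.3);")
    scene = cm.homogeneous_scene(tree, gc_model)
    sA, sB = 5, 40
    aln = CodonAlignment(names=["A", "B"], codons=np.array([[sA], [sB]]))
    b = next(b for b in tree.branches if tree.name[b] == "B")
    post = joint_endpoint_posteriors(scene, aln, b)
    J = post.site(0)
    assert J.sum() == pytest.approx(1.0)
    assert J[sA, sB] == pytest.approx(1.0)


def test_joint_posterior_matches_brute_force(gc_model):
    tree = cm.tree_from_newick("((A:0.2,B:0.3):0.1,C:0.4);")
    R = cm.codon_frequencies(cm.f1x4_from_gc(0.7))
    scene = cm.homogeneous_scene(tree, gc_model, R)
    aln = CodonAlignment(names=["A", "B", "C"], codons=np.array([[4], [9], [50]]))
    internal = next(
        i for i in range(tree.n_nodes) if tree.children[i] and i != tree.root
    )
    P = {b: scene.model_of(b).transition_matrix(tree.length[b]) for b in tree.branches}
    leaf = {tree.name[i]: i for i in tree.leaves}
    # brute force joint over (root state, internal state)
    J = np.zeros((61, 61))
    for xr in range(61):
        for xi in range(61):
            J[xr, xi] = (
                R[xr]
                * P[internal][xr, xi]
                * P[leaf["A"]][xi, 4]
                * P[leaf["B"]][xi, 9]
                * P[leaf["C"]][xr, 50]
            )
    J /= J.sum()
    post = joint_endpoint_posteriors(scene, aln, internal)
    np.testing.assert_allclose(post.site(0), J, atol=1e-12)
    # marginal over the bottom state equals the posterior at the top node
    top_marginal = post.site(0).sum(axis=1)
    np.testing.assert_allclose(top_marginal, J.sum(axis=1), atol=1e-12)
    # a leaf branch below the internal node (upper flow crosses two levels)
    JA = np.zeros((61, 61))
    for xi in range(61):
        w = sum(
            R[xr] * P[internal][xr, xi] * P[leaf["C"]][xr, 50] for xr in range(61)
        )
        JA[xi, 4] = w * P[leaf["A"]][xi, 4] * P[leaf["B"]][xi, 9]
    JA /= JA.sum()
    postA = joint_endpoint_posteriors(scene, aln, leaf["A"])
    np.testing.assert_allclose(postA.site(0), JA, atol=1e-12)


def test_neutral_prior_branch_gives_t_over_3(code):
    """With no data (all-missing leaves) the posterior is the prior, and a
    neutral stationary branch of length t yields dN = dS = t/3 exactly."""
    neutral = cm.build_yn98(cm.YN98Parameters(2.0, 1.0, cm.f1x4_from_gc(0.4)))
    t = 0.7
    tree = cm.tree_from_newick(f"(A:{t},B:0.1);")
    scene = cm.homogeneous_scene(tree, neutral)
    aln = CodonAlignment(names=["A", "B"], codons=np.full((2, 1), -1))
    b = next(b for b in tree.branches if tree.name[b] == "A")
    res = branch_dnds(scene, aln, b)
    assert res.dN == pytest.approx(t / 3, abs=1e-10)
    assert res.dS == pytest.approx(t / 3, abs=1e-10)
    assert res.ratio == pytest.approx(1.0, abs=1e-10)


def test_count_conservation_on_branch(gc_model):
    """Summed over labels, posterior expected counts equal the expected
    total substitution count (all single-step changes counted at once)."""
    tree = cm.tree_from_newick("(A:0.4,B:0.2);")
    scene = cm.homogeneous_scene(tree, gc_model)
    rng = np.random.default_rng(2)
    aln = CodonAlignment(names=["A", "B"], codons=rng.integers(0, 61, (2, 30)))
    from codonmap.mapping import (
        _branch_flows,
        _posterior_expectation,
        spectral_integral,
    )

    flows = _branch_flows(scene, aln)
    b = tree.branches[0]
    res = branch_dnds(scene, aln, b, _flows=flows)
    partials, U, weights, inv, n_pat = flows
    P = gc_model.transition_matrix(tree.length[b])
    C_total = gc_model.Q - np.diag(np.diag(gc_model.Q))
    Mtot = spectral_integral(gc_model, C_total, tree.length[b])
    per_pat, _ = _posterior_expectation(U[b], partials[b], P, Mtot)
    assert res.count_syn + res.count_nonsyn == pytest.approx(
        float(weights @ per_pat), rel=1e-8
    )


def test_zero_length_branch_flags_undefined_ratio(gc_model):
    tree = cm.tree_from_newick("(A:0.0,B:0.3);")
    scene = cm.homogeneous_scene(tree, gc_model)
    aln = CodonAlignment(names=["A", "B"], codons=np.array([[5], [5]]))
    b = next(b for b in tree.branches if tree.name[b] == "A")
    res = branch_dnds(scene, aln, b)
    assert res.dS == 0.0 and res.dN == 0.0
    assert res.undefined_ratio and res.ratio is None
    # the instantaneous ability at the node is still reported
    assert res.ability_syn > 0


def test_aggregate_single_branch_identity(gc_model):
    tree = cm.tree_from_newick("(A:0.4,B:0.2);")
    scene = cm.homogeneous_scene(tree, gc_model)
    rng = np.random.default_rng(4)
    aln = CodonAlignment(names=["A", "B"], codons=rng.integers(0, 61, (2, 10)))
    res = map_tree(scene, aln)
    one = aggregate_dnds(res[:1])
    assert one.dN == res[0].dN and one.dS == res[0].dS
    assert one.ratio == pytest.approx(res[0].ratio)
    with pytest.raises(ValueError):
        aggregate_dnds([])


def test_aggregate_refinement_invariance(gc_model):
    """Splitting a branch with a degree-2 node preserves the path law, so
    expected counts and integrated abilities are exactly additive, and the
    summed dN/dS is preserved to the (small) extent that the mean neutral
    ability varies along the branch."""
    plain = cm.tree_from_newick("(A:0.4,B:0.2);")
    split = cm.tree_from_newick("((A:0.25):0.15,B:0.2);")
    R = cm.codon_frequencies(cm.f1x4_from_gc(0.6))
    sim = cm.SimulationScene(
        scene=cm.homogeneous_scene(plain, gc_model, R), n_codons=300, seed=9
    )
    aln = cm.simulate(sim).alignment
    res_plain = map_tree(cm.homogeneous_scene(plain, gc_model, R), aln)
    res_split = map_tree(cm.homogeneous_scene(split, gc_model, R), aln)
    to_A_plain = [r for r in res_plain if r.branch_name == "A"]
    to_A_split = [r for r in res_split if r.branch_name != "B"]
    # exact: counts and time-integrated abilities add up
    assert sum(r.count_nonsyn for r in to_A_split) == pytest.approx(
        to_A_plain[0].count_nonsyn, rel=1e-8
    )
    assert sum(r.ability_syn * r.length for r in to_A_split) == pytest.approx(
        to_A_plain[0].ability_syn * to_A_plain[0].length, rel=1e-8
    )
    # near-exact: the per-branch normalized rates
    agg_plain = aggregate_dnds(to_A_plain)
    agg_split = aggregate_dnds(to_A_split)
    assert agg_split.dN == pytest.approx(agg_plain.dN, rel=0.02)
    assert agg_split.dS == pytest.approx(agg_plain.dS, rel=0.02)


def test_aggregate_mean_ratio_mode(gc_model):
    tree = cm.tree_from_newick("(A:0.4,B:0.2);")
    scene = cm.homogeneous_scene(tree, gc_model)
    rng = np.random.default_rng(12)
    aln = CodonAlignment(names=["A", "B"], codons=rng.integers(0, 61, (2, 10)))
    res = map_tree(scene, aln)
    mr = aggregate_dnds(res, mode="mean-ratio")
    assert mr.ratio == pytest.approx(np.mean([r.ratio for r in res]))


def test_per_nucleotide_factor_is_three():
    assert NUCLEOTIDES_PER_CODON == 3.0
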