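r"""Stochastic substitution mapping and the neutral-normalized dN/dS estimator.

For a branch of length t with generator Q and endpoint states (x, y), the
expected number of label-L substitutions conditional on the endpoints is

    E[N_L | x, y, t] = [ I_C(t) ]_{xy} / P_{xy}(t),
    I_C(t) = \int_0^t exp(Qs) C exp(Q(t-s)) ds,   C = Q restricted to L,

and the expected time spent weighted by a per-state reward r (here the
instantaneous neutral ability of label L) uses the same integral with
C = diag(r). Both are evaluated in closed form through the spectral
decomposition of Q; an independent uniformization series is provided as a
cross-check and alternative backend.

On real data the endpoints of a branch are unknown; they are integrated
out against their joint posterior given the whole alignment, the tree and
the (fitted) model — this is stochastic mapping. Writing E(N_L | b) for
the posterior expected count of L-events on branch b summed over sites,
and A0_L(b) for the posterior time-averaged instantaneous ability of the
neutral model M0 (the fitted model with omega = 1) summed over sites, the
per-branch rates are

    dN = E(N_nonsyn | b) / (3 * A0_nonsyn(b)),
    dS = E(N_syn | b)    / (3 * A0_syn(b)).

The factor NUCLEOTIDES_PER_CODON = 3 converts the per-codon rate
normalization of the models into the conventional per-nucleotide-site
scale of dN and dS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson

from .genetic_code import SubstitutionLabel
from .model import EIGEN_GAP_TOL, CodonModel, neutral_counterpart
from .phylo import (
    CodonAlignment,
    PhyloScene,
    _downward_partials,
    _pattern_states,
)

#: per-nucleotide normalization of dN and dS (applied exactly once, here)
NUCLEOTIDES_PER_CODON = 3.0

#: joint-posterior entries below this are skipped in dense double sums
POSTERIOR_FLOOR = 1e-14


# ---------------------------------------------------------------------------
# Endpoint-conditioned integrals
# ---------------------------------------------------------------------------


def spectral_integral(model: CodonModel, C: np.ndarray, t: float) -> np.ndarray:
    """Closed-form I_C(t) = int_0^t exp(Qs) C exp(Q(t-s)) ds.

    Uses the cached eigendecomposition Q = right @ diag(w) @ left. Pairs
    of eigenvalues closer than EIGEN_GAP_TOL take the confluent limit
    t * exp(w t).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    w = model.eigvals
    G = model.left @ C @ model.right
    dw = w[:, None] - w[None, :]
    close = np.abs(dw) < EIGEN_GAP_TOL
    ew = np.exp(w * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        J = (ew[:, None] - ew[None, :]) / dw
    mid = np.exp(0.5 * (w[:, None] + w[None, :]) * t)
    J[close] = (t * mid)[close]
    return model.right @ (G * J) @ model.left


def uniformization_integral(
    model: CodonModel, C: np.ndarray, t: float, tail: float = 1e-12
) -> np.ndarray:
    """I_C(t) via the uniformization series (independent of the spectral
    route): with mu = max_i (-Q_ii), Rm = I + Q/mu,

        I_C(t) = sum_n  Pois(n; mu t) * t/(n+1) * sum_{j<=n} Rm^j C Rm^{n-j}.

    The series is truncated when the remaining Poisson tail mass drops
    below `tail`.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    n_states = model.Q.shape[0]
    if t == 0:
        return np.zeros((n_states, n_states))
    mu = float(np.max(-np.diag(model.Q)))
    Rm = np.eye(n_states) + model.Q / mu
    n_max = int(poisson.isf(tail, mu * t)) + 2
    # S_n = sum_{j=0..n} Rm^j C Rm^{n-j}, built by the recursion
    # S_n = Rm @ S_{n-1} + C @ Rm^n
    out = np.zeros((n_states, n_states))
    S = C.copy()
    Rn = np.eye(n_states)
    pmf = poisson.pmf(np.arange(n_max + 1), mu * t)
    out += pmf[0] * t * S
    for n in range(1, n_max + 1):
        Rn = Rn @ Rm
        S = Rm @ S + C @ Rn
        out += pmf[n] * t / (n + 1.0) * S
    return out


def _label_generator(model: CodonModel, label: SubstitutionLabel) -> np.ndarray:
    return model.labeled_rates(label)


def expected_count_matrix(
    model: CodonModel,
    label: SubstitutionLabel,
    t: float,
    method: str = "spectral",
) -> np.ndarray:
    """Unnormalized endpoint matrix of expected L-counts: entry (x, y) is
    E[N_L ; X_t = y | X_0 = x] (divide by P_xy(t) to condition)."""
    C = _label_generator(model, label)
    if method == "spectral":
        return spectral_integral(model, C, t)
    if method == "uniformization":
        return uniformization_integral(model, C, t)
    raise ValueError(f"unknown method {method!r}")


def expected_reward_matrix(
    model: CodonModel,
    reward: np.ndarray,
    t: float,
    method: str = "spectral",
) -> np.ndarray:
    """Unnormalized endpoint matrix of E[int_0^t r(X_s) ds ; X_t = y | X_0 = x]
    for a per-state reward vector r (Minin–Suchard dwell times)."""
    C = np.diag(np.asarray(reward, float))
    if method == "spectral":
        return spectral_integral(model, C, t)
    return uniformization_integral(model, C, t)


def conditional_expected_count(
    model: CodonModel,
    label: SubstitutionLabel,
    t: float,
    x: int,
    y: int,
    method: str = "spectral",
) -> float:
    """E[number of L-substitutions on [0, t] | X_0 = x, X_t = y]."""
    P = model.transition_matrix(t)
    if P[x, y] <= 0 or (t == 0 and x != y):
        raise ValueError(f"endpoint pair ({x}, {y}) unreachable in time {t}")
    M = expected_count_matrix(model, label, t, method=method)
    return float(M[x, y] / P[x, y])


def conditional_expected_ability(
    model: CodonModel,
    neutral: CodonModel,
    label: SubstitutionLabel,
    t: float,
    x: int,
    y: int,
    method: str = "spectral",
) -> float:
    """E[int_0^t a_L^{M0}(X_s) ds | X_0 = x, X_t = y]: the time-integrated
    instantaneous ability of the neutral model along the branch, with the
    path law given by `model`."""
    P = model.transition_matrix(t)
    if P[x, y] <= 0 or (t == 0 and x != y):
        raise ValueError(f"endpoint pair ({x}, {y}) unreachable in time {t}")
    r = neutral.ability_vector(label)
    M = expected_reward_matrix(model, r, t, method=method)
    return float(M[x, y] / P[x, y])


# ---------------------------------------------------------------------------
# Posterior machinery on the tree
# ---------------------------------------------------------------------------


def _upward_partials(scene: PhyloScene, partials, n_pat):
    """Preorder 'upper' partial likelihoods U[i]: the likelihood flow at the
    top of branch i from everything outside the subtree below i, including
    the root distribution."""
    tree = scene.tree
    n_states = partials[0].shape[1]
    U = [None] * tree.n_nodes
    U[tree.root] = np.broadcast_to(
        scene.root_distribution, (n_pat, n_states)
    ).copy()
    for i in reversed(range(tree.n_nodes)):  # preorder (root last in postorder)
        if not tree.children[i]:
            continue
        if i == tree.root:
            at_node = U[i]
        else:
            # transport the flow at the top of branch i down to node i
            P_i = scene.model_of(i).transition_matrix(tree.length[i])
            at_node = U[i] @ P_i
        lifted = {}
        for c in tree.children[i]:
            P = scene.model_of(c).transition_matrix(tree.length[c])
            lifted[c] = partials[c] @ P.T
        for c in tree.children[i]:
            acc = at_node.copy()
            for s in tree.children[i]:
                if s != c:
                    acc = acc * lifted[s]
            m = acc.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            U[c] = acc / m[:, None]  # scaling cancels in posterior ratios
    return U


def _branch_flows(scene: PhyloScene, alignment: CodonAlignment):
    """Per-branch (U_top, L_bottom, weights): everything needed to take
    posterior expectations of endpoint functionals on each branch."""
    states, weights, inv, n_pat = _pattern_states(scene, alignment)
    partials, _ = _downward_partials(scene, states, n_pat)
    U = _upward_partials(scene, partials, n_pat)
    return partials, U, weights, inv, n_pat


@dataclass
class JointEndpointPosterior:
    """Joint posterior of the states at the two ends of a branch, per site."""

    branch: int
    matrices: np.ndarray  # (n_sites, n_states, n_states), rows: top state

    def site(self, s: int) -> np.ndarray:
        return self.matrices[s]


def joint_endpoint_posteriors(
    scene: PhyloScene, alignment: CodonAlignment, branch: int
) -> JointEndpointPosterior:
    """P(state at top, state at bottom | data) for every site of `branch`."""
    partials, U, weights, inv, n_pat = _branch_flows(scene, alignment)
    model = scene.model_of(branch)
    P = model.transition_matrix(scene.tree.length[branch])
    top, bot = U[branch], partials[branch]
    joint = top[:, :, None] * P[None, :, :] * bot[:, None, :]
    Z = joint.sum(axis=(1, 2), keepdims=True)
    joint /= Z
    return JointEndpointPosterior(branch=branch, matrices=joint[inv])


# ---------------------------------------------------------------------------
# Branch dN/dS
# ---------------------------------------------------------------------------


@dataclass
class BranchMappingResult:
    """Mapping summary for one branch.

    Counts are posterior expected numbers of events summed over sites;
    abilities are posterior time-averaged instantaneous neutral abilities
    summed over sites (so `ability * t` is the integrated reward). dN and
    dS are per nucleotide site: count / (3 * ability). `ratio` is
    dN/dS, or None when dS is 0 (`undefined_ratio` is then set).
    """

    branch: int
    branch_name: str
    length: float
    n_sites: int
    count_syn: float
    count_nonsyn: float
    ability_syn: float
    ability_nonsyn: float
    dN: float
    dS: float
    ratio: float | None
    undefined_ratio: bool = False
    per_site: dict = field(default_factory=dict, repr=False)

    @property
    def count_total(self) -> float:
        return self.count_syn + self.count_nonsyn


def _posterior_expectation(top, bot, P, M):
    """Per-pattern posterior expectation of an endpoint functional:
    sum_xy U_x M_xy L_y / sum_xy U_x P_xy L_y."""
    Z = np.einsum("px,xy,py->p", top, P, bot)
    num = np.einsum("px,xy,py->p", top, M, bot)
    return num / Z, Z


def branch_dnds(
    scene: PhyloScene,
    alignment: CodonAlignment,
    branch: int,
    neutral: CodonModel | None = None,
    renormalize_neutral: bool = True,
    keep_per_site: bool = False,
    _flows=None,
) -> BranchMappingResult:
    """Stochastic-mapping dN, dS and dN/dS for one branch.

    The path law is the branch's (fitted) model; the normalization uses
    the neutral counterpart M0 (omega = 1) of that model unless an
    explicit ability model is passed via `neutral`.
    """
    tree = scene.tree
    t = float(tree.length[branch])
    model = scene.model_of(branch)
    M0 = neutral if neutral is not None else neutral_counterpart(
        model, renormalize=renormalize_neutral
    )
    flows = _flows if _flows is not None else _branch_flows(scene, alignment)
    partials, U, weights, inv, n_pat = flows
    top, bot = U[branch], partials[branch]
    P = model.transition_matrix(t)

    per_pattern = {}
    for label in SubstitutionLabel:
        Mc = expected_count_matrix(model, label, t)
        counts, Z = _posterior_expectation(top, bot, P, Mc)
        r = M0.ability_vector(label)
        if t > 0:
            Ma = expected_reward_matrix(model, r, t)
            abil, _ = _posterior_expectation(top, bot, P, Ma)
            abil = abil / t  # time-average along the branch
        else:
            # zero-length branch: ability is the instantaneous one at the node
            post = top * bot
            post /= post.sum(axis=1, keepdims=True)
            abil = post @ r
            counts = np.zeros(n_pat)
        per_pattern[label] = (counts, abil)

    cs, asyn = per_pattern[SubstitutionLabel.SYNONYMOUS]
    cn, anon = per_pattern[SubstitutionLabel.NONSYNONYMOUS]
    count_syn = float(weights @ cs)
    count_nonsyn = float(weights @ cn)
    ability_syn = float(weights @ asyn)
    ability_nonsyn = float(weights @ anon)

    dN = count_nonsyn / (NUCLEOTIDES_PER_CODON * ability_nonsyn) if ability_nonsyn > 0 else 0.0
    dS = count_syn / (NUCLEOTIDES_PER_CODON * ability_syn) if ability_syn > 0 else 0.0
    undefined = dS == 0.0
    ratio = None if undefined else dN / dS

    per_site = {}
    if keep_per_site:
        per_site = {
            "count_syn": cs[inv],
            "count_nonsyn": cn[inv],
            "ability_syn": asyn[inv],
            "ability_nonsyn": anon[inv],
        }

    return BranchMappingResult(
        branch=branch,
        branch_name=tree.branch_name(branch),
        length=t,
        n_sites=alignment.n_sites,
        count_syn=count_syn,
        count_nonsyn=count_nonsyn,
        ability_syn=ability_syn,
        ability_nonsyn=ability_nonsyn,
        dN=dN,
        dS=dS,
        ratio=ratio,
        undefined_ratio=undefined,
        per_site=per_site,
    )


def map_tree(
    scene: PhyloScene,
    alignment: CodonAlignment,
    branches: list | None = None,
    renormalize_neutral: bool = True,
    keep_per_site: bool = False,
) -> list:
    """branch_dnds for every (or the selected) branch, sharing one pass of
    the likelihood machinery."""
    flows = _branch_flows(scene, alignment)
    todo = branches if branches is not None else scene.tree.branches
    return [
        branch_dnds(
            scene,
            alignment,
            b,
            renormalize_neutral=renormalize_neutral,
            keep_per_site=keep_per_site,
            _flows=flows,
        )
        for b in todo
    ]


@dataclass
class AggregateResult:
    dN: float
    dS: float
    ratio: float | None
    n_branches: int
    undefined_ratio: bool = False


def aggregate_dnds(results: list, mode: str = "sum") -> AggregateResult:
    """Clade-level dN, dS and dN/dS from per-branch results.

    mode "sum" (default): dN and dS are summed over branches and the
    ratio is sum(dN)/sum(dS). mode "mean-ratio": the ratio is instead the
    mean of the defined per-branch ratios.
    """
    if not results:
        raise ValueError("need at least one branch result")
    dN = float(sum(r.dN for r in results))
    dS = float(sum(r.dS for r in results))
    if mode == "sum":
        undefined = dS == 0.0
        ratio = None if undefined else dN / dS
    elif mode == "mean-ratio":
        ratios = [r.ratio for r in results if r.ratio is not None]
        undefined = not ratios
        ratio = None if undefined else float(np.mean(ratios))
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return AggregateResult(
        dN=dN, dS=dS, ratio=ratio, n_branches=len(results), undefined_ratio=undefined
    )
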