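"""Shared fixtures and independent oracles for the test suite.

The Monte-Carlo path oracle and the brute-force likelihood oracle are
written from first principles here (plain Gillespie simulation and
explicit state-space enumeration) so that they are independent of the
spectral/uniformization/pruning code paths they validate.
"""

import numpy as np
import pytest

import codonmap as cm
from codonmap.genetic_code import SubstitutionLabel


@pytest.fixture(scope="session")
def code():
    return cm.STANDARD_CODE


@pytest.fixture(scope="session")
def uniform_model():
    """YN98 with kappa=2, omega=0.3 and uniform nucleotide frequencies."""
    fp = cm.FrequencyParameterization("F1X4", np.full(4, 0.25))
    return cm.build_yn98(cm.YN98Parameters(2.0, 0.3, fp))


@pytest.fixture(scope="session")
def gc_model():
    return cm.build_yn98(cm.YN98Parameters(2.0, 0.5, cm.f1x4_from_gc(0.4)))


def gillespie_paths(Q, code, x0, t, n_paths, rng, reward_syn=None, reward_nonsyn=None):
    """Vectorized Gillespie simulation of `n_paths` independent site paths
    from state x0 over [0, t].

    Returns endpoint states, per-path synonymous/nonsynonymous jump counts
    and, if reward vectors are given, per-path integrated rewards. Written
    directly from the jump-chain construction (no package simulation code).
    """
    n = Q.shape[0]
    exit_rate = -np.diag(Q)
    jump_cdf = np.cumsum(
        np.where(np.eye(n, dtype=bool), 0.0, Q) / exit_rate[:, None], axis=1
    )
    state = np.full(n_paths, x0, dtype=np.int64)
    clock = np.zeros(n_paths)
    n_syn = np.zeros(n_paths, dtype=np.int64)
    n_non = np.zeros(n_paths, dtype=np.int64)
    r_syn = np.zeros(n_paths)
    r_non = np.zeros(n_paths)
    active = np.ones(n_paths, dtype=bool)
    while active.any():
        idx = np.nonzero(active)[0]
        s = state[idx]
        wait = rng.exponential(1.0 / exit_rate[s])
        dwell = np.minimum(wait, t - clock[idx])
        if reward_syn is not None:
            r_syn[idx] += reward_syn[s] * dwell
            r_non[idx] += reward_nonsyn[s] * dwell
        done = clock[idx] + wait >= t
        clock[idx] += wait
        active[idx[done]] = False
        jumping = idx[~done]
        if jumping.size:
            u = rng.random(jumping.size)
            nxt = (u[:, None] > jump_cdf[state[jumping]]).sum(axis=1)
            syn = code.is_synonymous[state[jumping], nxt]
            n_syn[jumping] += syn
            n_non[jumping] += ~syn
            state[jumping] = nxt
    return state, n_syn, n_non, r_syn, r_non


def mc_conditional(model, x0, t, n_paths, seed=0):
    """Endpoint-conditioned Monte-Carlo estimates from `n_paths` Gillespie
    paths started at x0: for each endpoint y, mean and standard error of
    syn/nonsyn counts and integrated neutral-ability rewards."""
    M0 = cm.neutral_counterpart(model)
    rng = np.random.default_rng(seed)
    end, ns, nn, rs, rn = gillespie_paths(
        model.Q,
        model.code,
        x0,
        t,
        n_paths,
        rng,
        reward_syn=M0.ability_vector(SubstitutionLabel.SYNONYMOUS),
        reward_nonsyn=M0.ability_vector(SubstitutionLabel.NONSYNONYMOUS),
    )
    out = {}
    for y in np.unique(end):
        sel = end == y
        m = sel.sum()
        stats = {}
        for key, v in (("n_syn", ns), ("n_non", nn), ("r_syn", rs), ("r_non", rn)):
            vals = v[sel].astype(float)
            stats[key] = (vals.mean(), vals.std(ddof=1) / np.sqrt(m) if m > 1 else np.inf)
        stats["n_accepted"] = m
        out[int(y)] = stats
    return out


def brute_force_loglik(scene, alignment):
    """Likelihood by explicit summation over all internal-node states
    (feasible for <= 3-leaf trees)."""
    tree = scene.tree
    n = next(iter(scene.branch_models.values())).code.n_states
    P = {b: scene.model_of(b).transition_matrix(tree.length[b]) for b in tree.branches}
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    leaf_row = {i: alignment.names.index(tree.name[i]) for i in tree.leaves}
    total = 0.0
    for s in range(alignment.n_sites):
        obs = {i: alignment.codons[leaf_row[i], s] for i in tree.leaves}
        tot = 0.0
        for assign in np.ndindex(*([n] * len(internal))):
            states = dict(zip(internal, assign))
            states.update(obs)
            p = scene.root_distribution[states[tree.root]]
            for b in tree.branches:
                x = states[tree.parent[b]]
                y = states[b]
                if y == -1:
                    continue  # missing leaf marginalizes out
                p *= P[b][x, y]
            tot += p
        total += np.log(tot)
    return total
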