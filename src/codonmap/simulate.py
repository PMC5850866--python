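"""Simulation of codon alignments under (non)stationary, branch-
heterogeneous YN98 models, with ground-truth substitution records.

Sequences evolve site-independently: the root sequence is drawn i.i.d.
from the root distribution and each branch applies an exact
continuous-time Markov (Gillespie) simulation per site, classifying and
counting every jump as synonymous or nonsynonymous. The recorded
per-branch counts are the ground truth against which the mapping
expectations are validated.

The bundled 6-taxon mammalian topology (two primates plus macaque,
mouse/rat, dog) is the default simulation tree; its branch lengths are
configurable and default to 0.1 substitutions per codon (0.05 on the
short primate-internal branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_code import STANDARD_CODE, GeneticCode, SubstitutionLabel
from .model import CodonModel, YN98Parameters, build_yn98
from .phylo import CodonAlignment, PhyloScene, RootedTree, tree_from_newick
from .genetic_code import f1x4_from_gc, codon_frequencies


def mammalian_fixture_tree(
    branch_length: float = 0.1, primate_internal: float = 0.05
) -> RootedTree:
    """Rooted 6-taxon tree (((human,chimp),macaque),(mouse,rat),dog)."""
    b, p = branch_length, primate_internal
    newick = (
        f"(((human:{b},chimp:{b}):{p},macaque:{b}):{b},"
        f"(mouse:{b},rat:{b}):{b},dog:{b});"
    )
    return tree_from_newick(newick)


@dataclass
class SimulationScene:
    """Inputs of one simulation: a PhyloScene, sequence length and seed."""

    scene: PhyloScene
    n_codons: int
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


@dataclass
class SimulationRecord:
    """Output of one simulation: the leaf alignment, ancestral sequences and
    per-branch true event counts (and time-integrated true abilities of the
    simulating model, when requested)."""

    alignment: CodonAlignment
    ancestral: dict  # node index -> codon index array
    branch_counts: dict  # node index -> {SubstitutionLabel: int}
    branch_abilities: dict = field(default_factory=dict)
    scene: SimulationScene | None = None


def sample_root(R: np.ndarray, n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. codon draws from the root distribution R."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    return rng.choice(len(R), size=n_codons, p=R)


def evolve_branch(
    seq: np.ndarray,
    model: CodonModel,
    t: float,
    rng: np.random.Generator,
    record_ability: bool = False,
):
    """Exact per-site Gillespie simulation of one branch.

    Returns (new sequence, {label: event count}) and, if requested, a third
    element: the realized time-integral of the per-label instantaneous
    rates of `model` along all site paths.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    code = model.code
    exit_rate = -np.diag(model.Q)
    # jump chain: row-normalized off-diagonal rates
    jump = model.Q.copy()
    np.fill_diagonal(jump, 0.0)
    rowsum = jump.sum(axis=1, keepdims=True)
    # absorbing states (e.g. ATG when omega = 0) are never left; any row works
    jump = np.divide(jump, rowsum, out=np.full_like(jump, 1.0 / jump.shape[0]),
                     where=rowsum > 0)
    syn_rate = model.ability_vector(SubstitutionLabel.SYNONYMOUS)
    non_rate = model.ability_vector(SubstitutionLabel.NONSYNONYMOUS)

    out = seq.copy()
    counts = {SubstitutionLabel.SYNONYMOUS: 0, SubstitutionLabel.NONSYNONYMOUS: 0}
    abil = {SubstitutionLabel.SYNONYMOUS: 0.0, SubstitutionLabel.NONSYNONYMOUS: 0.0}
    for i in range(len(seq)):
        s = int(out[i])
        clock = 0.0
        while True:
            rate = exit_rate[s]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            dwell = min(wait, t - clock)
            if record_ability:
                abil[SubstitutionLabel.SYNONYMOUS] += syn_rate[s] * dwell
                abil[SubstitutionLabel.NONSYNONYMOUS] += non_rate[s] * dwell
            clock += wait
            if clock >= t:
                break
            nxt = int(rng.choice(len(exit_rate), p=jump[s]))
            if code.is_synonymous[s, nxt]:
                counts[SubstitutionLabel.SYNONYMOUS] += 1
            else:
                counts[SubstitutionLabel.NONSYNONYMOUS] += 1
            s = nxt
        out[i] = s
    if record_ability:
        return out, counts, abil
    return out, counts


def simulate(sim: SimulationScene, record_ability: bool = False) -> SimulationRecord:
    """Recursive preorder simulation from the root along the tree."""
    scene = sim.scene
    tree = scene.tree
    rng = np.random.default_rng(sim.seed)
    seqs = {tree.root: sample_root(scene.root_distribution, sim.n_codons, rng)}
    branch_counts = {}
    branch_abilities = {}
    for i in reversed(range(tree.n_nodes)):  # preorder
        for c in tree.children[i]:
            res = evolve_branch(
                seqs[i],
                scene.model_of(c),
                float(tree.length[c]),
                rng,
                record_ability=record_ability,
            )
            if record_ability:
                seqs[c], branch_counts[c], branch_abilities[c] = res
            else:
                seqs[c], branch_counts[c] = res
    code = next(iter(scene.branch_models.values())).code
    leaves = tree.leaves
    alignment = CodonAlignment(
        names=[tree.name[i] for i in leaves],
        codons=np.array([seqs[i] for i in leaves]),
        code=code,
    )
    return SimulationRecord(
        alignment=alignment,
        ancestral={i: seqs[i] for i in range(tree.n_nodes) if tree.children[i]},
        branch_counts=branch_counts,
        branch_abilities=branch_abilities,
        scene=sim,
    )


def gc_drift_scene(
    theta_root: float,
    theta_eq: float,
    omega: float,
    kappa: float = 2.0,
    tree: RootedTree | None = None,
    n_codons: int = 1000,
    seed: int = 0,
    heterogeneous: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> SimulationScene:
    """The grid scenario: root composition at G+C = theta_root, evolving
    toward a YN98+F1X4 equilibrium at G+C = theta_eq.

    With ``heterogeneous=True`` the primate clade instead keeps a
    stationary composition at theta_root while only the dog and rodent
    branches drift toward theta_eq (the heterogeneous-dynamics scenario).
    """
    tree = tree if tree is not None else mammalian_fixture_tree()
    R = codon_frequencies(f1x4_from_gc(theta_root), code)
    drift = build_yn98(YN98Parameters(kappa, omega, f1x4_from_gc(theta_eq)), code=code)
    if not heterogeneous:
        models = {b: drift for b in tree.branches}
    else:
        stay = build_yn98(
            YN98Parameters(kappa, omega, f1x4_from_gc(theta_root)), code=code
        )
        primate = set(tree.clade_branches(["human", "chimp", "macaque"]))
        models = {b: (stay if b in primate else drift) for b in tree.branches}
    scene = PhyloScene(tree=tree, branch_models=models, root_distribution=R)
    return SimulationScene(
        scene=scene,
        n_codons=n_codons,
        seed=seed,
        meta={
            "theta_root": theta_root,
            "theta_eq": theta_eq,
            "omega": omega,
            "kappa": kappa,
            "heterogeneous": heterogeneous,
        },
    )


def grid_scenes(
    theta_root_values=tuple(np.round(np.arange(0.1, 0.95, 0.1), 1)),
    theta_eq_values=tuple(np.round(np.arange(0.1, 0.95, 0.1), 1)),
    omega_values=(0.1, 0.9, 1.0, 1.1),
    tree: RootedTree | None = None,
    n_codons: int = 1000,
    replicates: int = 10,
    seed: int = 0,
):
    """Deterministic enumeration of grid simulation scenes.

    The default grid follows the simulation-study design: both G+C axes
    run 0.1..0.9 in steps of 0.1 and omega covers negative, weakly
    negative, neutral and weakly positive selection (0.1, 0.9, 1, 1.1).
    Per-scene seeds are derived reproducibly from the master seed.
    """
    if not (len(theta_root_values) and len(theta_eq_values) and len(omega_values)):
        raise ValueError("value lists must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(
        len(theta_root_values) * len(theta_eq_values) * len(omega_values) * replicates
    )
    k = 0
    for tr in theta_root_values:
        for te in theta_eq_values:
            for om in omega_values:
                for rep in range(replicates):
                    child_seed = int(children[k].generate_state(1)[0] % (2**31))
                    k += 1
                    sc = gc_drift_scene(
                        tr, te, om, tree=tree, n_codons=n_codons, seed=child_seed
                    )
                    sc.meta["replicate"] = rep
                    yield sc
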