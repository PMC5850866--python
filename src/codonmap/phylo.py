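"""Rooted trees, codon alignments and nonstationary phylogenetic likelihood.

The likelihood is the standard pruning recursion over the 61 sense-codon
states, generalized in two ways: the distribution at the root is a free
parameter R (nonstationary models let R differ from the equilibrium of
the process), and each branch may carry its own substitution model
(nonhomogeneous models). Because the root distribution matters, trees are
never re-rooted implicitly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from scipy.stats import chi2

from .genetic_code import STANDARD_CODE, GeneticCode
from .model import CodonModel

MISSING = -1


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class RootedTree:
    """A rooted tree in postorder arrays.

    Nodes are indexed 0..n-1 in postorder (root last). `parent[i]` is the
    parent index (-1 for the root), `length[i]` the length of the branch
    above node i (expected substitutions per codon), `children[i]` the
    child indices and `name[i]` the node label ('' if unnamed). Branches
    are identified by their child node.
    """

    parent: np.ndarray
    length: np.ndarray
    children: list
    name: list

    @property
    def n_nodes(self) -> int:
        return len(self.name)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def branches(self) -> list:
        """All non-root nodes, i.e. all branches, in postorder."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]

    def leaf_names(self) -> list:
        return [self.name[i] for i in self.leaves]

    def branch_name(self, i: int) -> str:
        return self.name[i] or f"node{i}"

    def clade_branches(self, mrca_names: list) -> list:
        """Branch (child-node) indices of the full clade spanned by the
        leaves named in `mrca_names`, including the stem branch."""
        want = set(mrca_names)
        below = [set() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if not self.children[i]:
                below[i] = {self.name[i]}
            else:
                for c in self.children[i]:
                    below[i] |= below[c]
        mrca = min(
            (i for i in range(self.n_nodes) if want <= below[i]),
            key=lambda i: len(below[i]),
        )
        out = []
        stack = list(self.children[mrca])
        while stack:
            j = stack.pop()
            out.append(j)
            stack.extend(self.children[j])
        if self.parent[mrca] >= 0:
            out.append(mrca)
        return sorted(out)

    def total_length(self) -> float:
        return float(self.length[self.branches].sum())


def tree_from_newick(newick: str) -> RootedTree:
    """Parse a rooted Newick string (branch lengths required on non-root
    nodes; missing lengths default to 0)."""
    dt = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    nodes = list(dt.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    children: list = [[] for _ in range(n)]
    names = []
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
            children[parent[i]].append(i)
            length[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if nd.taxon is not None:
            names.append(nd.taxon.label)
        else:
            names.append(nd.label or "")
    if np.any(length < 0) or not np.all(np.isfinite(length)):
        raise ValueError("branch lengths must be finite and >= 0")
    leaf_names = [names[i] for i in range(n) if not children[i]]
    if len(set(leaf_names)) != len(leaf_names):
        raise ValueError("leaf names must be unique")
    return RootedTree(parent=parent, length=length, children=children, name=names)


def tree_to_newick(tree: RootedTree) -> str:
    def render(i: int) -> str:
        if not tree.children[i]:
            s = tree.name[i]
        else:
            s = "(" + ",".join(render(c) for c in tree.children[i]) + ")" + tree.name[i]
        if tree.parent[i] >= 0:
            s += f":{tree.length[i]:.10g}"
        return s

    return render(tree.root) + ";"


def read_tree(path) -> RootedTree:
    with open(path) as fh:
        return tree_from_newick(fh.read())


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """An in-frame codon alignment encoded over sense-codon indices.

    `codons` has shape (n_sequences, n_sites) with entries in [0, 61) or
    MISSING (-1) for gaps/ambiguities. Sequence names must match the leaf
    labels of the tree they are analysed with.
    """

    names: list
    codons: np.ndarray
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE, repr=False)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    @classmethod
    def from_sequences(cls, named_seqs, code: GeneticCode = STANDARD_CODE):
        names, rows = [], []
        length = None
        for name, seq in named_seqs:
            seq = str(seq).upper().replace("U", "T")
            if length is None:
                length = len(seq)
                if length % 3 != 0:
                    raise ValueError(
                        f"alignment length {length} is not divisible by 3; "
                        "supply an in-frame codon alignment"
                    )
            elif len(seq) != length:
                raise ValueError("sequences must have equal length")
            row = np.empty(length // 3, dtype=np.int32)
            for s in range(0, length, 3):
                triplet = seq[s : s + 3]
                if triplet in code.index:
                    row[s // 3] = code.index[triplet]
                elif triplet in code.stop_codons:
                    raise ValueError(
                        f"in-frame stop codon {triplet} at position {s} in {name!r}"
                    )
                else:
                    row[s // 3] = MISSING  # gap or ambiguity -> missing data
            names.append(name)
            rows.append(row)
        return cls(names=names, codons=np.array(rows), code=code)

    @classmethod
    def read_fasta(cls, path, code: GeneticCode = STANDARD_CODE):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls.from_sequences(records, code=code)

    def to_fasta(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_fasta_string())

    def to_fasta_string(self) -> str:
        out = io.StringIO()
        for name, row in zip(self.names, self.codons):
            out.write(f">{name}\n")
            seq = "".join(
                self.code.sense_codons[c] if c >= 0 else "---" for c in row
            )
            out.write(seq + "\n")
        return out.getvalue()

    def patterns(self):
        """Unique site patterns and their multiplicities (columns over leaves)."""
        cols = self.codons.T
        uniq, inv, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True
        )
        return uniq.T, counts.astype(float), inv


# ---------------------------------------------------------------------------
# Scenes: tree + per-branch models + root distribution
# ---------------------------------------------------------------------------


@dataclass
class PhyloScene:
    """Everything the likelihood needs: a rooted tree, one CodonModel per
    branch (by child-node index) and the root codon distribution R."""

    tree: RootedTree
    branch_models: dict  # node index -> CodonModel
    root_distribution: np.ndarray

    def __post_init__(self):
        for b in self.tree.branches:
            if b not in self.branch_models:
                raise ValueError(f"branch {b} has no model assigned")
        R = np.asarray(self.root_distribution, float)
        if abs(R.sum() - 1.0) > 1e-8 or np.any(R < -1e-12):
            raise ValueError("root distribution must be a probability vector")

    def model_of(self, branch: int) -> CodonModel:
        return self.branch_models[branch]


def homogeneous_scene(
    tree: RootedTree, model: CodonModel, root_distribution: np.ndarray | None = None
) -> PhyloScene:
    """One model on every branch; stationary if R is omitted (R = pi)."""
    R = model.pi if root_distribution is None else root_distribution
    return PhyloScene(
        tree=tree,
        branch_models={b: model for b in tree.branches},
        root_distribution=R,
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _leaf_partial(states: np.ndarray, n_states: int) -> np.ndarray:
    n_pat = states.shape[0]
    L = np.zeros((n_pat, n_states))
    obs = states >= 0
    L[np.arange(n_pat)[obs], states[obs]] = 1.0
    L[~obs, :] = 1.0  # missing data: marginalize
    return L


def _downward_partials(scene: PhyloScene, pattern_states: dict, n_pat: int):
    """Postorder conditional likelihoods with per-node log-scaling.

    Returns (partials, logscale) where partials[i] is (n_pat, 61) and
    logscale[i] the accumulated per-pattern log scaling of subtree i.
    """
    tree = scene.tree
    n_states = next(iter(scene.branch_models.values())).code.n_states
    partials = [None] * tree.n_nodes
    logscale = [None] * tree.n_nodes
    for i in range(tree.n_nodes):
        if not tree.children[i]:
            partials[i] = _leaf_partial(pattern_states[i], n_states)
            logscale[i] = np.zeros(n_pat)
        else:
            acc = np.ones((n_pat, n_states))
            ls = np.zeros(n_pat)
            for c in tree.children[i]:
                P = scene.model_of(c).transition_matrix(tree.length[c])
                acc *= partials[c] @ P.T
                ls += logscale[c]
            m = acc.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            acc /= m[:, None]
            partials[i] = acc
            logscale[i] = ls + np.log(m)
    return partials, logscale


def _pattern_states(scene: PhyloScene, alignment: CodonAlignment):
    tree = scene.tree
    leaf_rows = {name: k for k, name in enumerate(alignment.names)}
    missing = set(tree.leaf_names()) - set(alignment.names)
    if missing:
        raise ValueError(f"leaves absent from alignment: {sorted(missing)}")
    pats, weights, inv = alignment.patterns()
    states = {}
    for i in tree.leaves:
        states[i] = pats[leaf_rows[tree.name[i]]]
    return states, weights, inv, pats.shape[1]


def site_log_likelihoods(scene: PhyloScene, alignment: CodonAlignment) -> np.ndarray:
    """Per-site log-likelihoods (in alignment site order)."""
    states, _, inv, n_pat = _pattern_states(scene, alignment)
    partials, logscale = _downward_partials(scene, states, n_pat)
    root = scene.tree.root
    site = partials[root] @ scene.root_distribution
    ll_pat = np.log(site) + logscale[root]
    return ll_pat[inv]


def total_log_likelihood(scene: PhyloScene, alignment: CodonAlignment) -> float:
    """Sum of site log-likelihoods (sites independent)."""
    if alignment.n_sites == 0:
        return 0.0
    states, weights, _, n_pat = _pattern_states(scene, alignment)
    partials, logscale = _downward_partials(scene, states, n_pat)
    root = scene.tree.root
    site = partials[root] @ scene.root_distribution
    return float(weights @ (np.log(site) + logscale[root]))


# ---------------------------------------------------------------------------
# Tests on fitted likelihoods
# ---------------------------------------------------------------------------


def likelihood_ratio_test(ll0: float, ll1: float, df: int, tol: float = 1e-6) -> float:
    """Upper-tail chi-square p-value for nested models (ll1: richer model)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (ll1 - ll0)
    if stat < -tol:
        raise ValueError(
            f"richer model has lower likelihood (2*dll = {stat:.3g}); "
            "models are not nested or not converged"
        )
    return float(chi2.sf(max(stat, 0.0), df))


def benjamini_hochberg(pvalues, fdr: float = 0.01):
    """Benjamini-Hochberg step-up procedure.

    Returns (reject flags, adjusted p-values) in the input order. The
    default FDR level is 1%.
    """
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, padj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject, padj
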