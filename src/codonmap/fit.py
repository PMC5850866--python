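"""Maximum-likelihood fitting of stationary and nonstationary YN98 scenes.

Three nested templates are supported:

* ``stationary-homogeneous`` — one YN98 model on every branch, root
  distribution tied to the model's equilibrium (R = pi).
* ``nonstationary-homogeneous`` — one model, but the root composition is
  a free frequency parameterization.
* ``nonstationary-nonhomogeneous`` — branches are partitioned into groups,
  each with its own kappa, omega and equilibrium frequencies, plus a free
  root composition.

Optimization is box-constrained quasi-Newton (L-BFGS-B) on transformed
parameters: log for branch lengths, kappa and omega; additive-log-ratio
for frequency parameters. Multiple starts (data-informed defaults plus
random jitter) mitigate local optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .genetic_code import STANDARD_CODE, FrequencyParameterization, GeneticCode
from .model import YN98Parameters, build_yn98
from .phylo import (
    CodonAlignment,
    PhyloScene,
    RootedTree,
    total_log_likelihood,
)

TEMPLATES = (
    "stationary-homogeneous",
    "nonstationary-homogeneous",
    "nonstationary-nonhomogeneous",
)

LOG_BL_BOUNDS = (np.log(1e-6), np.log(20.0))
LOG_KAPPA_BOUNDS = (np.log(0.05), np.log(50.0))
LOG_OMEGA_BOUNDS = (np.log(1e-3), np.log(50.0))
ALR_BOUNDS = (-12.0, 12.0)


def _alr_to_freqs(x: np.ndarray) -> np.ndarray:
    """Additive-log-ratio -> probability vector (last component is baseline)."""
    z = np.concatenate([x, [0.0]])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _freqs_to_alr(f: np.ndarray) -> np.ndarray:
    f = np.clip(np.asarray(f, float), 1e-6, None)
    return np.log(f[:-1] / f[-1])


def _fp_from_alr(x: np.ndarray, scheme: str) -> FrequencyParameterization:
    if scheme == "F1X4":
        return FrequencyParameterization("F1X4", _alr_to_freqs(x))
    rows = np.stack([_alr_to_freqs(x[3 * p : 3 * p + 3]) for p in range(3)])
    return FrequencyParameterization("F3X4", rows)


def _fp_n_free(scheme: str) -> int:
    return 3 if scheme == "F1X4" else 9


def empirical_nucleotide_freqs(
    alignment: CodonAlignment, scheme: str, code: GeneticCode = STANDARD_CODE
) -> FrequencyParameterization:
    """Observed nucleotide composition of the alignment, pooled (F1X4) or
    per codon position (F3X4), with a small pseudocount."""
    obs = alignment.codons[alignment.codons >= 0]
    nucs = code.codon_nucs[obs]  # (n_obs_codons, 3)
    counts = np.ones((3, 4))
    for p in range(3):
        counts[p] += np.bincount(nucs[:, p], minlength=4)
    counts /= counts.sum(axis=1, keepdims=True)
    if scheme == "F1X4":
        return FrequencyParameterization("F1X4", counts.mean(axis=0))
    return FrequencyParameterization("F3X4", counts)


@dataclass
class ModelTemplate:
    """Declarative description of a fit: template name, frequency scheme and
    (for nonhomogeneous fits) a branch partition {group name: branch ids}."""

    kind: str
    scheme: str = "F1X4"
    partition: dict | None = None

    def __post_init__(self):
        if self.kind not in TEMPLATES:
            raise ValueError(f"unknown template {self.kind!r}")
        if self.kind == "nonstationary-nonhomogeneous" and not self.partition:
            raise ValueError("nonhomogeneous template requires a branch partition")
        if self.kind != "nonstationary-nonhomogeneous":
            self.partition = None

    @property
    def nonstationary(self) -> bool:
        return self.kind != "stationary-homogeneous"

    def groups(self, tree: RootedTree) -> dict:
        if self.partition is None:
            return {"all": list(tree.branches)}
        seen: list = []
        for branches in self.partition.values():
            seen.extend(branches)
        if sorted(seen) != sorted(tree.branches):
            raise ValueError("partition must cover every branch exactly once")
        return {g: list(b) for g, b in self.partition.items()}

    def n_parameters(self, tree: RootedTree) -> int:
        """Free-parameter count: branch lengths, per-group (kappa, omega,
        frequency parameters), plus root frequencies if nonstationary."""
        k = _fp_n_free(self.scheme)
        n = len(tree.branches)
        n += len(self.groups(tree)) * (2 + k)
        if self.nonstationary:
            n += k
        return n


@dataclass
class FitResult:
    """Outcome of an ML fit."""

    template: ModelTemplate
    log_likelihood: float
    branch_lengths: np.ndarray  # indexed by branch (child-node) id
    group_params: dict  # group -> YN98Parameters
    root_freqs: FrequencyParameterization | None
    tree: RootedTree
    n_parameters: int
    converged: bool
    n_evaluations: int
    message: str = ""
    start_log_likelihoods: list = field(default_factory=list)

    @property
    def omega(self) -> float:
        """Fitted omega (of the single group, for homogeneous templates)."""
        if len(self.group_params) != 1:
            raise ValueError("omega is per-group for nonhomogeneous fits")
        return next(iter(self.group_params.values())).omega

    def scene(self) -> PhyloScene:
        """Fitted PhyloScene (tree with fitted branch lengths, per-branch
        models, fitted root distribution)."""
        tree = replace(self.tree, length=self.branch_lengths.copy())
        groups = self.template.groups(self.tree)
        models = {}
        for g, params in self.group_params.items():
            m = build_yn98(params)
            for b in groups[g]:
                models[b] = m
        if self.root_freqs is not None:
            from .genetic_code import codon_frequencies

            R = codon_frequencies(self.root_freqs)
        else:
            R = next(iter(models.values())).pi
        return PhyloScene(tree=tree, branch_models=models, root_distribution=R)


class _Packer:
    """Maps between the structured parameters and the flat optimizer vector."""

    def __init__(self, template: ModelTemplate, tree: RootedTree):
        self.template = template
        self.tree = tree
        self.branches = list(tree.branches)
        self.groups = template.groups(tree)
        self.k = _fp_n_free(template.scheme)

    def pack(self, bl, group_params, root_fp):
        x = [np.log(np.clip(bl[self.branches], 1e-6, 20.0))]
        for g in self.groups:
            p = group_params[g]
            x.append([np.log(p.kappa), np.log(p.omega)])
            x.append(_freqs_to_alr_scheme(p.equilibrium_freqs))
        if self.template.nonstationary:
            x.append(_freqs_to_alr_scheme(root_fp))
        return np.concatenate([np.atleast_1d(v) for v in x])

    def unpack(self, x: np.ndarray):
        nb = len(self.branches)
        bl = np.zeros(self.tree.n_nodes)
        bl[self.branches] = np.exp(x[:nb])
        pos = nb
        group_params = {}
        for g in self.groups:
            kappa, omega = np.exp(x[pos]), np.exp(x[pos + 1])
            fp = _fp_from_alr(x[pos + 2 : pos + 2 + self.k], self.template.scheme)
            group_params[g] = YN98Parameters(kappa, omega, fp)
            pos += 2 + self.k
        root_fp = None
        if self.template.nonstationary:
            root_fp = _fp_from_alr(x[pos : pos + self.k], self.template.scheme)
        return bl, group_params, root_fp

    def bounds(self):
        b = [LOG_BL_BOUNDS] * len(self.branches)
        for _ in self.groups:
            b += [LOG_KAPPA_BOUNDS, LOG_OMEGA_BOUNDS] + [ALR_BOUNDS] * self.k
        if self.template.nonstationary:
            b += [ALR_BOUNDS] * self.k
        return b


def _freqs_to_alr_scheme(fp: FrequencyParameterization) -> np.ndarray:
    if fp.scheme == "F1X4":
        return _freqs_to_alr(fp.freqs)
    return np.concatenate([_freqs_to_alr(row) for row in fp.freqs])


def _scene_from(template, tree, bl, group_params, root_fp) -> PhyloScene:
    from .genetic_code import codon_frequencies

    t = replace(tree, length=bl)
    groups = template.groups(tree)
    models = {}
    for g, params in group_params.items():
        m = build_yn98(params)
        for b in groups[g]:
            models[b] = m
    R = (
        codon_frequencies(root_fp)
        if root_fp is not None
        else next(iter(models.values())).pi
    )
    return PhyloScene(tree=t, branch_models=models, root_distribution=R)


def fit_ml(
    alignment: CodonAlignment,
    tree: RootedTree,
    template: ModelTemplate | str = "nonstationary-homogeneous",
    n_starts: int = 3,
    seed: int = 0,
    init_kappa: float = 2.0,
    init_omega: float = 0.5,
    maxiter: int = 1000,
    ftol: float = 1e-9,
) -> FitResult:
    """Fit a YN98 scene by maximum likelihood.

    Branch lengths, kappa and omega (per group), equilibrium frequency
    parameters (per group) and — for nonstationary templates — the root
    frequency parameters are all free. The first start uses the supplied
    tree lengths and the alignment's empirical nucleotide composition;
    further starts jitter the transformed parameters.
    """
    if isinstance(template, str):
        template = ModelTemplate(template)
    packer = _Packer(template, tree)
    emp = empirical_nucleotide_freqs(alignment, template.scheme)

    base_params = {
        g: YN98Parameters(init_kappa, init_omega, emp) for g in packer.groups
    }
    bl0 = np.clip(tree.length, 1e-4, 20.0)
    x0 = packer.pack(bl0, base_params, emp)

    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        try:
            bl, gp, rfp = packer.unpack(x)
            scene = _scene_from(template, tree, bl, gp, rfp)
            ll = total_log_likelihood(scene, alignment)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    best = None
    start_lls = []
    for s in range(max(1, n_starts)):
        x_start = x0 if s == 0 else x0 + rng.normal(0.0, 0.3, size=x0.shape)
        x_start = np.clip(
            x_start,
            [lo for lo, _ in packer.bounds()],
            [hi for _, hi in packer.bounds()],
        )
        res = minimize(
            objective,
            x_start,
            method="L-BFGS-B",
            bounds=packer.bounds(),
            options={"maxiter": maxiter, "ftol": ftol},
        )
        start_lls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res

    bl, gp, rfp = packer.unpack(best.x)
    return FitResult(
        template=template,
        log_likelihood=-best.fun,
        branch_lengths=bl,
        group_params=gp,
        root_freqs=rfp,
        tree=tree,
        n_parameters=template.n_parameters(tree),
        converged=bool(best.success),
        n_evaluations=n_eval,
        message=str(best.message),
        start_log_likelihoods=start_lls,
    )
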