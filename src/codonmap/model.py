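"""YN98 codon substitution models: generator construction, normalization,
spectral decomposition and instantaneous abilities.

The model follows Yang & Nielsen (1998): only single-nucleotide codon
changes have positive rate; a change x->y gets rate proportional to the
equilibrium frequency of y, multiplied by kappa if the nucleotide change
is a transition and by omega if the amino acid changes. The generator is
normalized so that a sequence at equilibrium accumulates one expected
substitution per codon per unit of time, which makes branch lengths
directly comparable across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_code import (
    STANDARD_CODE,
    FrequencyParameterization,
    GeneticCode,
    SubstitutionLabel,
    codon_frequencies,
)

#: frequencies below this floor are lifted so the chain stays irreducible
#: on all sense codons (uniform state indexing across branch models)
FREQ_FLOOR = 1e-12

#: eigenvalue gaps below this switch mapping integrals to the confluent form
EIGEN_GAP_TOL = 1e-9


@dataclass(frozen=True)
class YN98Parameters:
    """Free parameters of a YN98 model."""

    kappa: float
    omega: float
    equilibrium_freqs: FrequencyParameterization

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not self.omega >= 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")


@dataclass
class CodonModel:
    """A normalized codon substitution process with cached spectral data.

    Attributes
    ----------
    Q : (n, n) generator; off-diagonals >= 0, rows sum to 0.
    pi : equilibrium distribution of Q.
    scale : the constant the raw YN98 rates were divided by to reach one
        expected substitution per codon per unit time at equilibrium.
    eigvals, right, left : spectral decomposition Q = right @ diag(eigvals)
        @ left, obtained from the reversibility symmetrization (real
        spectrum guaranteed).
    """

    Q: np.ndarray
    pi: np.ndarray
    scale: float
    kappa: float
    omega: float
    equilibrium_freqs: FrequencyParameterization
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE, repr=False)
    eigvals: np.ndarray = field(default=None, repr=False)
    right: np.ndarray = field(default=None, repr=False)
    left: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.eigvals is None:
            self._decompose()

    def _decompose(self):
        # symmetrize: S = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        sqrt_pi = np.sqrt(self.pi)
        S = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)  # kill round-off asymmetry
        w, V = np.linalg.eigh(S)
        self.eigvals = w
        self.right = V / sqrt_pi[:, None]
        self.left = V.T * sqrt_pi[None, :]

    # ------------------------------------------------------------------

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1. Requires t >= 0."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        P = (self.right * np.exp(self.eigvals * t)) @ self.left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def ability_vector(self, label: SubstitutionLabel) -> np.ndarray:
        """Per-state instantaneous ability: a_L(s) = sum of Q[s, y] over the
        single-step targets y with classification `label`."""
        mask = self.code.label_mask(label)
        return np.where(mask, self.Q, 0.0).sum(axis=1)

    def labeled_rates(self, label: SubstitutionLabel) -> np.ndarray:
        """Q with all entries outside the label set zeroed (diagonal zero)."""
        return np.where(self.code.label_mask(label), self.Q, 0.0)

    def total_rate(self) -> float:
        """Equilibrium-weighted total substitution rate, -sum_i pi_i Q_ii.

        Equals 1 for a normalized model (one substitution per codon per
        unit time).
        """
        return float(-self.pi @ np.diag(self.Q))


def build_yn98(
    params: YN98Parameters,
    code: GeneticCode = STANDARD_CODE,
    normalize: bool = True,
    scale: float | None = None,
) -> CodonModel:
    """Construct a (by default normalized) YN98 codon model.

    Parameters
    ----------
    normalize : if True (default), divide the generator by the equilibrium
        substitution rate so the expected rate is 1 per codon per unit time.
    scale : if given, divide by this externally supplied constant instead
        (used when a neutral counterpart must inherit the scale of the
        selected model).
    """
    pi = codon_frequencies(params.equilibrium_freqs, code)
    pi = np.maximum(pi, FREQ_FLOOR)
    pi = pi / pi.sum()

    rates = np.where(code.n_diff == 1, pi[None, :], 0.0)
    rates = np.where(code.is_transition_pair, rates * params.kappa, rates)
    rates = np.where(code.is_nonsynonymous, rates * params.omega, rates)
    np.fill_diagonal(rates, 0.0)
    np.fill_diagonal(rates, -rates.sum(axis=1))

    raw_rate = float(-pi @ np.diag(rates))
    if scale is not None:
        applied = scale
    elif normalize:
        applied = raw_rate
    else:
        applied = 1.0
    Q = rates / applied

    return CodonModel(
        Q=Q,
        pi=pi,
        scale=applied,
        kappa=params.kappa,
        omega=params.omega,
        equilibrium_freqs=params.equilibrium_freqs,
        code=code,
    )


def neutral_counterpart(model: CodonModel, renormalize: bool = True) -> CodonModel:
    """The neutral model M0: same kappa and equilibrium frequencies, omega = 1.

    With ``renormalize=True`` (default) M0 is scaled to one expected
    substitution per codon per unit time at its own equilibrium, so its
    total ability is exactly 1. With ``renormalize=False`` M0 reuses the
    raw-rate scale of `model` instead.
    """
    params = YN98Parameters(
        kappa=model.kappa, omega=1.0, equilibrium_freqs=model.equilibrium_freqs
    )
    if renormalize:
        return build_yn98(params, code=model.code, normalize=True)
    return build_yn98(params, code=model.code, scale=model.scale)


def instantaneous_ability(
    model: CodonModel, state: str | int, label: SubstitutionLabel
) -> float:
    """Rate, from `state`, of substitutions in the label set under `model`."""
    idx = model.code.require_sense(state) if isinstance(state, str) else int(state)
    return float(model.ability_vector(label)[idx])
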