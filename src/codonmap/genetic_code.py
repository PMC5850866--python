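"""Genetic-code bookkeeping for codon substitution models.

The state space of every model in this package is the set of *sense*
codons (61 under the standard nuclear code), ordered lexicographically
over the nucleotide alphabet ``A < C < G < T`` with stop codons removed.
All generator matrices, frequency vectors and alignments use this fixed
indexing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: purine/pyrimidine partners: A<->G, C<->T
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


class Classification(enum.Enum):
    """Outcome of comparing an ordered pair of sense codons."""

    IDENTICAL = "identical"
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    MULTIPLE_HIT = "multiple_hit"


class SubstitutionLabel(enum.Enum):
    """Label sets used throughout mapping: L = syn or nonsyn events."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return _TRANSITION_PARTNER[a] == b


@dataclass
class GeneticCode:
    """A genetic code restricted to its sense codons.

    Parameters
    ----------
    table_id : int
        NCBI translation table identifier (default 1, the standard code).

    Attributes
    ----------
    sense_codons : list of str
        The non-stop triplets, lexicographic over A,C,G,T. 61 entries for
        the standard code.
    index : dict
        Triplet -> integer in ``[0, n_states)``.
    """

    table_id: int = 1
    codon_to_aa: dict = field(init=False, repr=False)
    stop_codons: frozenset = field(init=False, repr=False)
    sense_codons: list = field(init=False, repr=False)
    index: dict = field(init=False, repr=False)

    def __post_init__(self):
        table = CodonTable.unambiguous_dna_by_id[self.table_id]
        self.codon_to_aa = dict(table.forward_table)
        self.stop_codons = frozenset(table.stop_codons)
        all_codons = [
            a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
        ]
        self.sense_codons = [c for c in all_codons if c not in self.stop_codons]
        self.index = {c: i for i, c in enumerate(self.sense_codons)}
        self._build_tables()

    # -- derived lookup tables ------------------------------------------------

    def _build_tables(self):
        n = self.n_states
        codons = self.sense_codons
        # nucleotide index per codon position, shape (n, 3)
        self.codon_nucs = np.array(
            [[NUC_INDEX[c[p]] for p in range(3)] for c in codons], dtype=np.int8
        )
        diff = np.zeros((n, n), dtype=np.int8)
        for p in range(3):
            diff += self.codon_nucs[:, None, p] != self.codon_nucs[None, :, p]
        self.n_diff = diff
        aa = np.array([self.codon_to_aa[c] for c in codons])
        same_aa = aa[:, None] == aa[None, :]
        single = diff == 1
        self.is_synonymous = single & same_aa
        self.is_nonsynonymous = single & ~same_aa
        # transition indicator for single-difference pairs
        ts = np.zeros((n, n), dtype=bool)
        for i, x in enumerate(codons):
            for j, y in enumerate(codons):
                if diff[i, j] == 1:
                    p = int(np.nonzero(self.codon_nucs[i] != self.codon_nucs[j])[0][0])
                    ts[i, j] = is_transition(x[p], y[p])
        self.is_transition_pair = ts
        # target nucleotide of the changed position (for F3X4-style rates the
        # YN98 convention uses the full target codon frequency, so this table
        # is informational only)
        self.amino_acids = aa

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def label_mask(self, label: SubstitutionLabel) -> np.ndarray:
        """Boolean (n, n) indicator of the single-step pairs carrying `label`."""
        if label is SubstitutionLabel.SYNONYMOUS:
            return self.is_synonymous
        return self.is_nonsynonymous

    def require_sense(self, codon: str) -> int:
        """Index of a sense codon; raise ValueError for stops/invalid triplets."""
        codon = codon.upper().replace("U", "T")
        if codon in self.stop_codons:
            raise ValueError(f"{codon!r} is a stop codon, not a sense codon")
        if codon not in self.index:
            raise ValueError(f"{codon!r} is not a valid codon over ACGT")
        return self.index[codon]


#: module-level standard code, shared by default everywhere
STANDARD_CODE = GeneticCode()


def classify_pair(x: str, y: str, code: GeneticCode = STANDARD_CODE) -> Classification:
    """Classify the ordered codon pair (x, y).

    Returns IDENTICAL, SYNONYMOUS, NONSYNONYMOUS or MULTIPLE_HIT. Both
    codons must be sense codons of `code`. The SYN/NONSYN/MULTIPLE_HIT
    outcomes are symmetric in (x, y).
    """
    i, j = code.require_sense(x), code.require_sense(y)
    if i == j:
        return Classification.IDENTICAL
    if code.n_diff[i, j] > 1:
        return Classification.MULTIPLE_HIT
    if code.is_synonymous[i, j]:
        return Classification.SYNONYMOUS
    return Classification.NONSYNONYMOUS


@dataclass(frozen=True)
class FrequencyParameterization:
    """Codon frequencies as products of nucleotide frequencies.

    scheme "F1X4": one distribution over A,C,G,T shared by the three codon
    positions (3 free parameters). scheme "F3X4": three position-specific
    distributions (9 free parameters).
    """

    scheme: str
    freqs: np.ndarray  # shape (4,) for F1X4, (3, 4) for F3X4

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if self.scheme == "F1X4":
            if f.shape != (4,):
                raise ValueError("F1X4 expects 4 nucleotide frequencies")
            rows = f[None, :]
        elif self.scheme == "F3X4":
            if f.shape != (3, 4):
                raise ValueError("F3X4 expects a (3, 4) frequency array")
            rows = f
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if np.any(rows < -1e-12) or np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("each nucleotide distribution must be a probability vector")
        object.__setattr__(self, "freqs", f)

    def position_freqs(self) -> np.ndarray:
        """(3, 4) array of per-position nucleotide frequencies."""
        if self.scheme == "F1X4":
            return np.tile(self.freqs, (3, 1))
        return self.freqs


def gc_parameterization(theta: float) -> np.ndarray:
    """Symmetric nucleotide composition with G+C proportion `theta`.

    A = T = (1 - theta)/2 and G = C = theta/2, making theta the single
    compositional degree of freedom (the axis of the simulation grid).
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    at = (1.0 - theta) / 2.0
    gc = theta / 2.0
    return np.array([at, gc, gc, at])  # A, C, G, T


def f1x4_from_gc(theta: float) -> FrequencyParameterization:
    """F1X4 parameterization from a single G+C proportion."""
    return FrequencyParameterization("F1X4", gc_parameterization(theta))


def codon_frequencies(
    fp: FrequencyParameterization, code: GeneticCode = STANDARD_CODE
) -> np.ndarray:
    """Codon distribution over the sense codons implied by `fp`.

    Frequency of a codon is the product of its position-wise nucleotide
    frequencies; stop codons are dropped and the result renormalized to
    sum to one over the sense codons.
    """
    pos = fp.position_freqs()
    raw = (
        pos[0, code.codon_nucs[:, 0]]
        * pos[1, code.codon_nucs[:, 1]]
        * pos[2, code.codon_nucs[:, 2]]
    )
    total = raw.sum()
    if total <= 0:
        raise ValueError("all sense codons have zero frequency under this parameterization")
    return raw / total


def gc_content(freqs: np.ndarray, code: GeneticCode = STANDARD_CODE) -> float:
    """Expected G+C proportion of a codon distribution (over all 3 positions)."""
    is_gc = np.isin(code.codon_nucs, [NUC_INDEX["G"], NUC_INDEX["C"]])
    return float(freqs @ is_gc.sum(axis=1)) / 3.0
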