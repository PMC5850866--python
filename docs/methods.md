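# Methods

## Model

The substitution process on each branch is the Yang–Nielsen (1998) codon
model on the 61 sense codons of the standard nuclear genetic code (codons
ordered lexicographically over A < C < G < T, stops removed; alternative
NCBI translation tables are a `GeneticCode` constructor option but are not
exercised by the test suite). Off-diagonal rates are

    q(x→y) = π_y · κ^[transition] · ω^[nonsynonymous]   if x and y differ
                                                        at exactly one
                                                        nucleotide,
    q(x→y) = 0                                          otherwise,

where π is the equilibrium codon distribution, κ > 0 the
transition/transversion ratio and ω ≥ 0 the selection parameter. π is
parameterized as a product of nucleotide frequencies — one shared
distribution (F1X4, 3 free parameters) or three position-specific ones
(F3X4, 9 free parameters) — with stop-codon frequencies set to zero and
the remainder renormalized. Every generator is scaled to one expected
substitution per codon per unit time at its own equilibrium, so branch
lengths are expected substitutions per codon. Frequencies are floored at
1e−12 and renormalized rather than excluding zero-frequency states: the
chain stays irreducible and the 61-state indexing is uniform across branch
models.

Nonstationarity enters through a free root distribution R (same product
parameterization); nonhomogeneity through a partition of branches into
groups, each with its own (κ, ω, π). The likelihood is the pruning
recursion with per-node rescaling; missing data (gaps, ambiguities)
marginalize as all-ones partial vectors. Columns that are entirely missing
are kept — they contribute likelihood exactly 1, which is equivalent to
dropping them. Because the root distribution is a parameter, trees are
treated as genuinely rooted and never re-rooted; likelihood is invariant
to root placement only in the stationary, reversible special case (a
property the test suite asserts both ways).

## Stochastic mapping

For a branch of length t with generator Q, the joint density of the
endpoint states and any additive path functional is handled through the
integral I_C(t) = ∫₀ᵗ e^{Qs} C e^{Q(t−s)} ds with

* C = Q ∘ 1_L (off-diagonal entries of label L) for expected **counts** of
  L-events, and
* C = diag(r) for expected **dwell rewards**, with r the per-state
  instantaneous ability of the neutral model M0 to perform L-events
  (Minin–Suchard reward formulation).

I_C(t) is evaluated in closed form through the eigendecomposition of Q.
YN98 is reversible, so diag(√π) Q diag(1/√π) is symmetric and the spectrum
is real; the decomposition is computed once per model by `eigh` on the
symmetrized form. Eigenvalue pairs closer than 1e−9 use the confluent
limit t·e^{λt} of the divided difference. An independent uniformization
series (truncated where the Poisson tail mass drops below 1e−12) is
shipped as an alternative backend and pinned against the spectral route to
1e−8 relative error in the tests, alongside a rejection-sampling Gillespie
oracle implemented from first principles in the test suite.

On data, the endpoint states of a branch are integrated against their
joint posterior given the whole alignment (upper × transition × lower
partial likelihoods, normalized per site). Per branch and label the
package reports the posterior expected count summed over sites and the
posterior **time-averaged** neutral ability summed over sites, and forms

    dN = count_nonsyn / (3 · ability_nonsyn),
    dS = count_syn   / (3 · ability_syn).

Two conventions deserve a note. First, the denominator is the time-average
(integrated reward divided by t), not the raw integral: this is what makes
a neutral branch of length t yield dN = dS = t/3 — the count and the
ability coincide in expectation under M0, leaving t divided by the
per-nucleotide factor 3 — and it is asserted exactly in the tests via a
data-free (all-missing) branch. For a zero-length branch the ability
reported is the instantaneous one at the node and dS = dN = 0 with the
ratio flagged undefined rather than infinite. Second, M0 is by default
re-normalized to rate 1 at its own equilibrium; the alternative (inherit
the fitted model's scale, `renormalize_neutral=False`) is selectable and
changes dN and dS by a common factor, leaving dN/dS untouched. Clade-level
values sum dN and dS over branches and take the quotient; a mean-of-ratios
mode exists behind a flag. Summed counts and integrated abilities are
exactly additive under branch refinement; the normalized per-branch rates
are additive up to the (small) variation of the mean neutral ability along
a branch, which the tests bound at 2% on simulated data.

## Fitting

`fit_ml` maximizes the likelihood with L-BFGS-B on transformed parameters:
log branch lengths (bounded to [1e−6, 20]), log κ, log ω, and
additive-log-ratio frequency parameters (bounded to ±12). The first start
combines the input tree's branch lengths, κ = 2, ω = 0.5 and the
alignment's empirical nucleotide composition (pooled or per position);
additional starts (library default 3) jitter the transformed vector with
σ = 0.3. Convergence uses the optimizer's relative function tolerance of
1e−9 on the negative log-likelihood. Site patterns are compressed before
evaluation. Degrees of freedom for likelihood-ratio tests are derived from
the templates' own parameter counts (branch lengths + per-group (2 + 3 or
9) + root frequencies if nonstationary) rather than hard-coded;
Benjamini–Hochberg correction (default FDR 1%, configurable) is applied
across gene batches via statsmodels.

## Simulator

The simulator realizes the exact process: root codons drawn i.i.d. from R,
then per-site Gillespie simulation along each branch with every jump
classified and counted, optionally accumulating the realized time-integral
of the per-label rates. It records ancestral sequences and per-branch
ground-truth counts, which back the unbiasedness tests of the mapping
expectations. The grid driver enumerates the bias-study conditions —
root and equilibrium GC each from 0.1 to 0.9 in steps of 0.1 and
ω ∈ {0.1, 0.9, 1, 1.1} — with per-scene seeds derived from one master
seed. The heterogeneous scenario keeps the primate clade stationary at
the root composition while dog and rodent branches drift.

The bundled tree is the 6-taxon mammalian topology
(((human,chimp),macaque),(mouse,rat),dog) with configurable branch
lengths defaulting to 0.1 (0.05 for the primate-internal branch), i.e. a
total length of 0.85 expected substitutions per codon. Simulated data are
i.i.d. across sites and indel-free; real alignments add site-heterogeneous
selection, rate variation and alignment error that the simulation study
deliberately excludes, so green tests certify the estimator under the
model, not robustness to model violation.

## Study scale and expected magnitudes

The desk-scale study conditions are 10 replicates of 1000 codons per grid
cell with 2-start fits (the full-scale design of 100 replicates × 3000
codons is reachable through the same arguments). At these conditions the
nonstationary template recovers ω without detectable bias across the grid
(e.g. 0.103 ± 0.006 for ω = 0.1 with GC 0.8→0.2; 0.93 ± 0.03 for ω = 0.9
with GC 0.2→0.8), and the neutral pipeline returns a tree-aggregated
dN/dS within Monte-Carlo error of 1. The stationary-fit inflation of ω in
the extreme cell (GC 0.9→0.1, ω = 0.1) is reproduced in direction but its
magnitude depends on how much compositional drift the tree allows: with
the default total length of 0.85 the inflation is ≈1.3–1.7-fold, and
diagnostic runs show it growing toward 2-fold as branch lengths approach
mammalian scale (≈0.3 per branch). The corresponding acceptance test
asserts the 2-fold figure and therefore documents this gap rather than
hiding it.

## Known limitations

* Variances and higher moments of the mapped counts are not computed;
  the estimates come without confidence intervals.
* Only the one-shot mapping estimates are produced; no EM iteration on
  branch-specific ω.
* No site-heterogeneous selection models, rate variation across sites, or
  topology search; the tree is always user-supplied.
* The CLI's `map` subcommand reconstructs scenes from `fit.json` only for
  homogeneous fits; nonhomogeneous fit-and-map runs go through the Python
  API (`fit_ml(...).scene()` + `map_tree`).
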