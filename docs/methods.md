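# Methods

## Model

`pathorder` estimates the temporal order in which biological pathways acquire
functional somatic mutations during carcinogenesis, from a cross-sectional
cohort of tumors. The data per patient j are the counts Y_i^j of non-silent
mutations in each pathway category i (m_j = Σ_i Y_i^j in total) together with
one functional-impact score r_k per mutation — the probability, from an
annotation tool such as PolyPhen-2, that the mutation damages protein
function.

Two latent layers are marginalised out:

1. **Functional indicators.** Each mutation is functional (a driver event,
   S_k = 1) independently with probability r_k, so
   P(S_1..S_m | m) = Π_k r_k^{S_k} (1 − r_k)^{1 − S_k}.
2. **Orderings.** Functional mutations occur in a temporal sequence; the k-th
   functional event falls in category i with probability p_{k,i}, the (k,i)
   entry of the pivotal step matrix P (rows on the simplex). Passenger
   (non-functional) mutations are exchangeable and land in category i with
   probability q_i.

The marginal likelihood of a patient's counts sums, over the per-category
functional-count splits n = (n_i), the product of (a) a Poisson-binomial
weight per category (the probability that exactly n_i of the category's
mutations are functional, aggregating the 2^m indicator sum at polynomial
cost), (b) the total probability W(n) of all functional label sequences with
counts n, and (c) a passenger factor for the remaining counts. W(n) satisfies
the recursion W(n) = Σ_i p_{|n|,i} W(n − e_i) and is computed by one dynamic
program over the count lattice, never by sequence enumeration. A literal
enumeration oracle (`brute_force_likelihood`, m ≤ 8) validates the
factorisation exactly.

**K-truncation.** Rows beyond a depth K are tied, p_{k,·} = p_{K,·} for
k > K, so only the first K steps carry free parameters. Default K = 4;
`k_stability_diagnostic` reproduces the stability analysis supporting that
choice, and `functional_count_distribution` shows how little mass lies beyond
four functional events per pathway pair.

**Order probabilities.** For a pathway pair (A, B) regrouped into mutually
exclusive categories A′ = A∖B, AB = A∩B, B′ = B∖A, the probability that A is
altered first is the mass of sequences whose first event touching either
pathway lies in A′; a first event in AB alters both simultaneously and
carries P(A=B). These class probabilities are computed exactly by an
absorbing forward pass over the steps (validated against exhaustive
3^horizon classification), with horizon max_j m_j. A pathway never altered
within the horizon counts as altered later; a `require_both` flag implements
the stricter convention instead.

## Estimation

q is fixed first by the plug-in estimator
q_i = Σ_j E_i^j / Σ_j Σ_z E_z^j with E_z^j = Σ_{k in z} (1 − r_k), then the
cohort log-likelihood is maximised over P. Each row of P is reparameterised
by a softmax against a fixed reference category (the last), making the
problem unconstrained; Nelder–Mead runs from 5 starts (uniform rows, then
seeded Gaussian perturbations of scale 0.5 in omega space) with
xatol = fatol = 1e-6 and maxiter = 200 × dim. Identical patient profiles
(same counts and score multisets rounded to 1e-6) are collapsed with
multiplicity weights, and all split weights that do not depend on P are
precomputed, so one objective evaluation is a single lattice dynamic program
plus a matrix–vector product.

Note the plug-in q̂ pools (1 − r_k) over *all* mutations, so functional
mutations leak a small amount of their category distribution into q̂; with
boundary-concentrated scores the leakage is below 2% and negligible.

## Pairwise and joint analysis

By default every pair of pathways is analysed separately
(`fit_pairwise`): overlapping genes are regrouped into A′/AB/B′, mutations
outside the pair are discarded (an `include_other` bucket is available), and
patients with no in-pair mutations are dropped (their likelihood factor is
constant). `fit_joint` fits all pathways at once over atomic intersection
categories; its dynamic-programming state space is guarded by a budget with
a pointer back to pairwise mode. On simulated three-pathway cohorts the two
routes agree to within 0.1 in every order probability.

## Synthetic cohorts

`simulate_cohort` draws, per patient: a functional count and a passenger
count from configurable pmfs (defaults: Poisson(1.5) truncated to 0..6 and
Poisson(3.0) truncated to 0..15 — in-pair mutation loads typical of
non-hypermutated exomes); the k-th functional mutation's category from row k
of the truth step matrix; each passenger's category from q; and each
mutation's score from the arm of a Beta score model matching its hidden
status. The default truth puts first-step mass (0.70, 0.10, 0.20) on
(A′, AB, B′), fading toward B at later steps, so P(A<B) = 0.7.

**Score calibration.** The likelihood interprets r as P(mutation is
functional). For the generator to satisfy this, its score arms must be the
conditionals implied by drawing r from a base distribution g and setting
S ~ Bernoulli(r): functional scores ∝ r·g(r), passenger scores ∝ (1−r)·g(r),
with E_g[r] equal to the generator's functional mutation fraction. With
Beta(a, b) base this gives the arms Beta(a+1, b) and Beta(a, b+1)
(`ScoreModel.calibrated`); with Poisson counts the generator is then exactly
the model's marginal law. The default base Beta(0.02, 0.04) has mean 1/3
(matching the count distributions) and the strongly bimodal shape of real
PolyPhen-2 annotations, whose scores pile up at 0 and 1 with
class-conditional means near 0.96 and 0.02. Uncalibrated arms (e.g. the
swap of the two arms) remain available for sensitivity experiments and
demonstrate that the score channel, not the counts, carries the ordering
signal.

**A caveat the package makes explicit.** The printed likelihood sums each
latent configuration over all distinct orderings of functional and passenger
labels (the passenger factor carries a multinomial coefficient). For
mutations made distinguishable by interior scores this is not the exact
likelihood of the labelled data — the configuration-dependent factors
Π_i n_i!/n! and Π_i c_i!/c! do not cancel across the indicator sum. The two
forms coincide when every score is 0 or 1, i.e. in the bimodal regime of
real PolyPhen-2 annotations. The printed form is the default everywhere; the
`sequence_multiplicity=False` switch on the likelihood and on `fit_mle`
selects the exact labelled-data form for sensitivity analysis.

**What the generator does not emulate:** gene-level mutation rates and
hotspots, copy-number variation, intra-tumor heterogeneity, cohort
substructure (subtypes), and the dependence of scores on the mutated gene.
Passing simulation tests therefore show correctness of the estimator under
the model's own generative assumptions, not robustness to their violation.

## Bias harness and problem sizes

`evaluate_bias` simulates replicate cohorts at each requested size (seeds
split deterministically per size and replicate via `SeedSequence`), fits
each with the default 5-restart protocol, and reports the mean absolute
error of the three order probabilities against the truth values computed
from the truth step matrix by the same forward pass (never set
independently). The shipped harness uses 50 replicates at n = 50, 200, 800;
measured errors for P(A<B) at seed 0 are 0.087 / 0.045 / 0.022 — shrinking
with n as expected for a consistent estimator. At n = 50 roughly 78% of
patients carry any functional mutation, so about 39 first events inform a
three-way split; the resulting information bound (~0.06 mean absolute error
even with fully observed indicators) means small-sample errors just below
0.09 are intrinsic to these cohort conditions, not an optimisation artifact
(more restarts reproduce them).

## Visualization

The partial-order plot draws an edge A → B with weight P(A<B) — tail altered
first — and prunes edges below 0.4. (The two conventions "head altered
after the tail" and "head altered before the tail" appear in different
descriptions of such plots; this package states its choice here and in the
module docstring.) Pathways are grouped by exact correlation clustering:
similarity P(A=B), dissimilarity P(A<B) + P(A>B), optimum over all set
partitions (≤ 12 pathways; a greedy agglomerative mode beyond), ties broken
toward fewer clusters then lexicographically. Layers are longest-path ranks
on the majority-direction (> 0.5) tournament after breaking each cycle at
its lowest-weight edge — a deterministic rule chosen because the drawing,
not the inference, consumes it. DOT output is deterministic; rendering is
delegated to external tools.

## Defaults

| parameter | default | origin |
| --- | --- | --- |
| hyper-mutated removal fraction | 0.16 | standard top-16% cut for colorectal cohorts; ceiling count, ties by sample id |
| truncation depth K | 4 | stability of order probabilities for K ≥ 4 |
| edge pruning threshold | 0.4 | readability of the partial-order plot |
| missing missense score | 0.5 | maximally uninformative |
| truncating-variant score | 1.0 | presumed loss of function |
| Nelder–Mead restarts | 5 | uniform start plus 4 seeded perturbations |
| restart perturbation scale | 0.5 (omega) | covers the simplex without leaving the basin structure |
| xatol / fatol | 1e-6 | order probabilities are reported to ~3 decimals |

## Degenerate inputs and numerical edges

Identical pathway pairs are rejected (order not identifiable). A′ empty
under strict inclusion is kept as a zero-count category. If every score is
1 the passenger denominator vanishes and q falls back to uniform with a
warning. Patient likelihoods below 1e-300 are clipped with a warning; an
exactly zero likelihood propagates −inf and the optimiser treats the point
as infeasible. `probs_to_softmax` clips boundary probabilities to
[1e-8, 1−1e-8] with a warning. All randomness flows from a single seed
(simulation, restarts, replicate splitting), so every result in this
package is bit-for-bit reproducible from (inputs, seed).

## Limitations

Single-nucleotide variants only; no copy-number events, no intra-tumor
heterogeneity, no subtype stratification, no uncertainty quantification for
P̂ (point estimates only), and pathway gene sets are taken as given inputs.
The pairwise mode conditions each analysis on in-pair mutations; whether an
"other" bucket should absorb out-of-pair mutations is exposed as an option
because either convention is defensible.
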