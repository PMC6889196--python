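"""Marginal likelihood of pathway mutation counts over latent functional states and orderings.

The model: each non-silent mutation in a tumor carries a functional-impact
score ``r`` (the probability that it damages protein function, e.g. a
PolyPhen-2 score).  Functional mutations are assumed to occur in a temporal
sequence; the k-th functional mutation falls in pathway category ``i`` with
probability ``p_{k,i}`` (the pivotal step-probability matrix).  Non-functional
(passenger) mutations are exchangeable and land in category ``i`` with
probability ``q_i``.  The observed data per patient are the per-category
mutation counts and scores only; the functional indicators and the order of
events are latent and are marginalised out.

The marginal patient likelihood is evaluated by a factorisation: the sum over
binary functional-indicator vectors is grouped by the per-category functional
counts (a Poisson-binomial weight per category), and the sum over orderings is
a dynamic program over remaining-count states.  A literal enumeration oracle
(:func:`brute_force_likelihood`) is provided for validation at small sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import reduce
from typing import Mapping, Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "PatientProfile",
    "StepProbabilities",
    "NonFunctionalRates",
    "poisson_binomial_pmf",
    "interleaving_weight",
    "nonfunctional_weight",
    "patient_likelihood",
    "cohort_log_likelihood",
    "estimate_q",
    "brute_force_likelihood",
]

#: patient likelihoods below this are clipped (with a warning) before taking logs
LIKELIHOOD_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientProfile:
    """Per-patient category mutation counts and impact scores.

    ``counts[c]`` is the observed number of non-silent mutations in category
    ``c``; ``scores[c]`` the corresponding impact scores (sorted — the
    within-category order is irrelevant to the likelihood).
    """

    sample_id: str
    counts: Mapping[str, int]
    scores: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        counts = {c: int(n) for c, n in self.counts.items()}
        scores = {c: tuple(sorted(float(r) for r in self.scores.get(c, ()))) for c in counts}
        for c, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for category {c!r}")
            if len(scores[c]) != n:
                raise ValueError(
                    f"category {c!r}: {len(scores[c])} scores for count {n}"
                )
            if any(not (0.0 <= r <= 1.0) for r in scores[c]):
                raise ValueError(f"impact score outside [0, 1] in category {c!r}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "scores", scores)

    @property
    def total(self) -> int:
        """Total non-silent mutation count m_j."""
        return sum(self.counts.values())

    def all_scores(self) -> list[float]:
        return [r for c in sorted(self.scores) for r in self.scores[c]]


@dataclass(frozen=True)
class StepProbabilities:
    """Pivotal matrix P: ``probs[k-1, i]`` is the probability that the k-th
    functional mutation falls in category ``categories[i]``.

    Rows beyond the truncation depth K reuse row K (an averaged distribution
    for late functional events).
    """

    categories: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != len(self.categories):
            raise ValueError("probs must be (K, n_categories)")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("step probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ValueError("each row of P must sum to 1")
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "probs", probs)

    @property
    def K(self) -> int:
        return self.probs.shape[0]

    def row(self, k: int) -> np.ndarray:
        """Row for step k (1-based), with truncation p_{k,.} = p_{K,.} for k > K."""
        if k < 1:
            raise ValueError("step index is 1-based")
        return self.probs[min(k, self.K) - 1]

    def extended(self, n_steps: int) -> np.ndarray:
        """Rows for steps 1..n_steps as an (n_steps, C) array."""
        if n_steps <= self.K:
            return self.probs[:n_steps]
        tail = np.repeat(self.probs[-1:], n_steps - self.K, axis=0)
        return np.vstack([self.probs, tail])


@dataclass(frozen=True)
class NonFunctionalRates:
    """Passenger-mutation category probabilities q_i (sum to 1)."""

    categories: tuple[str, ...]
    q: np.ndarray
    per_patient_expected: Mapping[str, Mapping[str, float]] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (len(self.categories),):
            raise ValueError("q must have one entry per category")
        if np.any(q < 0) or not math.isclose(float(q.sum()), 1.0, abs_tol=1e-12):
            raise ValueError("q must be a probability vector summing to 1")
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "q", q)

    def rate(self, category: str) -> float:
        return float(self.q[self.categories.index(category)])


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(scores: Sequence[float]) -> np.ndarray:
    """PMF of the number of successes among independent Bernoulli(r_k) trials.

    Computed by iterative convolution; entry ``n`` is the probability that
    exactly ``n`` of the mutations are functional.
    """
    scores = [float(r) for r in scores]
    if any(not (0.0 <= r <= 1.0) for r in scores):
        raise ValueError("scores must lie in [0, 1]")
    pmf = np.ones(1)
    for r in scores:
        nxt = np.zeros(len(pmf) + 1)
        nxt[:-1] += pmf * (1.0 - r)
        nxt[1:] += pmf * r
        pmf = nxt
    return pmf


def _interleaving_lattice(dims: Sequence[int], P: StepProbabilities) -> np.ndarray:
    """All interleaving weights W(n) for 0 <= n_i < dims[i] in one forward pass.

    W(n) = sum over distinct label sequences with per-category counts n of
    prod_k p_{k, label_k}; satisfies W(n) = sum_i p_{|n|, i} W(n - e_i).
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != len(P.categories):
        raise ValueError("dims must match P categories")
    W = np.zeros(dims)
    W[(0,) * len(dims)] = 1.0
    total_max = sum(d - 1 for d in dims)
    rows = P.extended(max(total_max, 1))
    totals = reduce(np.add.outer, [np.arange(d) for d in dims]) if dims else np.zeros(())
    flat_totals = totals.ravel()
    order = np.argsort(flat_totals, kind="stable")
    strides = np.array(
        [int(np.prod(dims[i + 1:], dtype=int)) for i in range(len(dims))], dtype=int
    )
    Wf = W.ravel()
    idx_grid = [np.arange(d) for d in dims]
    grids = np.meshgrid(*idx_grid, indexing="ij") if dims else []
    coords = np.stack([g.ravel() for g in grids], axis=1) if dims else None
    for flat in order:
        t = int(flat_totals[flat])
        if t == 0:
            continue
        acc = 0.0
        row = rows[t - 1]
        for i in range(len(dims)):
            if coords[flat, i] > 0:
                acc += row[i] * Wf[flat - strides[i]]
        Wf[flat] = acc
    return Wf.reshape(dims)


def interleaving_weight(func_counts: Mapping[str, int], P: StepProbabilities) -> float:
    """Total probability of all functional-label sequences with the given counts.

    Uses the truncated step rows of ``P`` (row K reused beyond depth K);
    returns 1 for all-zero counts.
    """
    counts = tuple(int(func_counts.get(c, 0)) for c in P.categories)
    if any(n < 0 for n in counts):
        raise ValueError("counts must be non-negative")
    lattice = _interleaving_lattice([n + 1 for n in counts], P)
    return float(lattice[counts])


def nonfunctional_weight(
    nonfunc_counts: Mapping[str, int], q: NonFunctionalRates
) -> float:
    """Probability mass of all distinct passenger-label sequences with the
    given counts: multinomial coefficient times ``prod q_i^{c_i}``."""
    counts = [int(nonfunc_counts.get(c, 0)) for c in q.categories]
    if any(n < 0 for n in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        return 1.0
    coef = math.factorial(total)
    prob = 1.0
    for n, qi in zip(counts, q.q):
        coef //= math.factorial(n)
        prob *= float(qi) ** n
    return coef * prob


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def _split_weight_tensor(
    Y: np.ndarray,
    pbs: Sequence[np.ndarray],
    q: NonFunctionalRates,
    sequence_multiplicity: bool,
) -> np.ndarray:
    """Per-split weights multiplying the interleaving lattice W(n).

    With ``sequence_multiplicity`` (the printed model) every distinct ordering
    of the latent label sequences counts once:
    weight(n) = [prod_i PB_i(n_i)] * (m - sum n)! * prod_i q_i^{Y_i-n_i}/(Y_i-n_i)!.
    Without it, the likelihood is that of the labelled mutations themselves
    (each mutation distinguishable by its score), where the ordering
    multiplicities cancel:
    weight(n) = [prod_i PB_i(n_i) n_i!] / (sum n)! * prod_i q_i^{Y_i-n_i}.
    The two coincide when every score is 0 or 1; with interior scores they are
    different likelihoods (see the methods note).
    """
    m = int(Y.sum())
    vs = []
    for i in range(len(Y)):
        n = np.arange(Y[i] + 1)
        rem = Y[i] - n
        qi = float(q.q[i])
        if sequence_multiplicity:
            fact = np.array([math.factorial(r) for r in rem], dtype=float)
            vs.append(pbs[i] * np.power(qi, rem) / fact)
        else:
            fact_n = np.array([math.factorial(k) for k in n], dtype=float)
            vs.append(pbs[i] * fact_n * np.power(qi, rem))
    tensor = reduce(np.multiply.outer, vs)
    totals = reduce(np.add.outer, [np.arange(y + 1) for y in Y])
    if sequence_multiplicity:
        factor = np.array([math.factorial(m - t) for t in range(m + 1)], dtype=float)
    else:
        factor = np.array([1.0 / math.factorial(t) for t in range(m + 1)])
    return tensor * factor[totals]


def patient_likelihood(
    profile: PatientProfile,
    P: StepProbabilities,
    q: NonFunctionalRates,
    sequence_multiplicity: bool = True,
) -> float:
    """Marginal likelihood of one patient's counts under (P, q).

    Sums over per-category functional-count splits: the Poisson-binomial
    weight of each split times the interleaving weight of the functional
    sequence times the passenger weight of the remainder.  Equivalent to the
    literal enumeration over all 2^m indicator vectors and all orderings
    (see :func:`brute_force_likelihood`) at polynomial cost.
    ``sequence_multiplicity=False`` switches to the labelled-mutation
    likelihood in which ordering multiplicities cancel.
    """
    if profile.total < 1:
        raise ValueError("profile must contain at least one mutation")
    cats = P.categories
    if tuple(q.categories) != cats:
        raise ValueError("P and q category orders differ")
    Y = np.array([profile.counts.get(c, 0) for c in cats], dtype=int)
    pbs = [poisson_binomial_pmf(profile.scores.get(c, ())) for c in cats]
    W = _interleaving_lattice(Y + 1, P)
    weight = _split_weight_tensor(Y, pbs, q, sequence_multiplicity)
    return float(np.sum(weight * W))


def cohort_log_likelihood(
    profiles: Sequence[PatientProfile],
    P: StepProbabilities,
    q: NonFunctionalRates,
    sequence_multiplicity: bool = True,
) -> float:
    """Sum of log patient likelihoods; -inf if any patient has zero likelihood."""
    total = 0.0
    for prof in profiles:
        lik = patient_likelihood(prof, P, q, sequence_multiplicity)
        if lik <= 0.0:
            return float("-inf")
        if lik < LIKELIHOOD_FLOOR:
            warnings.warn(
                f"patient {prof.sample_id}: likelihood below {LIKELIHOOD_FLOOR:g}, clipped"
            )
            lik = LIKELIHOOD_FLOOR
        total += math.log(lik)
    return total


def estimate_q(
    profiles: Sequence[PatientProfile],
    categories: Sequence[str] | None = None,
) -> NonFunctionalRates:
    """Plug-in estimator of passenger rates.

    E_z^j = sum over mutations k in category z of patient j of (1 - r_k) is
    the expected passenger count; q_i pools these across the cohort:
    q_i = sum_j E_i^j / sum_j sum_z E_z^j.
    """
    if categories is None:
        categories = sorted({c for p in profiles for c in p.counts})
    categories = tuple(categories)
    per_patient: dict[str, dict[str, float]] = {}
    totals = np.zeros(len(categories))
    for prof in profiles:
        e = {}
        for i, c in enumerate(categories):
            ez = float(sum(1.0 - r for r in prof.scores.get(c, ())))
            e[c] = ez
            totals[i] += ez
        per_patient[prof.sample_id] = e
    denom = float(totals.sum())
    if denom <= 0.0:
        warnings.warn(
            "all impact scores equal 1: passenger rates undefined, using uniform q"
        )
        qv = np.full(len(categories), 1.0 / len(categories))
    else:
        qv = totals / denom
    return NonFunctionalRates(categories, qv, per_patient_expected=per_patient)


# ---------------------------------------------------------------------------
# literal enumeration oracle
# ---------------------------------------------------------------------------

def _sequence_sum_functional(labels: tuple[str, ...], P: StepProbabilities) -> float:
    idx = [P.categories.index(c) for c in labels]
    rows = P.extended(max(len(labels), 1))
    total = 0.0
    for perm in multiset_permutations(idx):
        prod = 1.0
        for k, i in enumerate(perm):
            prod *= rows[k, i]
        total += prod
    return total


def _sequence_sum_nonfunctional(labels: tuple[str, ...], q: NonFunctionalRates) -> float:
    idx = [q.categories.index(c) for c in labels]
    total = 0.0
    for perm in multiset_permutations(idx):
        prod = 1.0
        for i in perm:
            prod *= float(q.q[i])
        total += prod
    return total


def brute_force_likelihood(
    profile: PatientProfile,
    P: StepProbabilities,
    q: NonFunctionalRates,
    sequence_multiplicity: bool = True,
) -> float:
    """Literal marginalisation over all 2^m indicator vectors and all distinct
    orderings of functional and passenger labels.  Test oracle; exponential
    cost, refuses profiles with more than 8 mutations.

    With ``sequence_multiplicity=False`` the functional order-sum is averaged
    over the distinct sequences and the passenger factor is the plain product
    of q's (the labelled-mutation likelihood)."""
    m = profile.total
    if m > 8:
        raise ValueError("brute force limited to profiles with at most 8 mutations")
    if m < 1:
        raise ValueError("profile must contain at least one mutation")
    muts = [
        (c, r) for c in sorted(profile.scores) for r in profile.scores[c]
    ]
    func_cache: dict[tuple[str, ...], float] = {}
    nonf_cache: dict[tuple[str, ...], float] = {}
    total = 0.0
    for mask in range(2 ** m):
        weight = 1.0
        func: list[str] = []
        nonf: list[str] = []
        for k, (cat, r) in enumerate(muts):
            if mask >> k & 1:
                weight *= r
                func.append(cat)
            else:
                weight *= 1.0 - r
                nonf.append(cat)
        if weight == 0.0:
            continue
        fkey = tuple(sorted(func))
        nkey = tuple(sorted(nonf))
        if fkey not in func_cache:
            fsum = 1.0 if not fkey else _sequence_sum_functional(fkey, P)
            if not sequence_multiplicity and fkey:
                counts = {c: fkey.count(c) for c in set(fkey)}
                n_seq = math.factorial(len(fkey))
                for c in counts.values():
                    n_seq //= math.factorial(c)
                fsum /= n_seq
            func_cache[fkey] = fsum
        if nkey not in nonf_cache:
            if not nkey:
                nsum = 1.0
            elif sequence_multiplicity:
                nsum = _sequence_sum_nonfunctional(nkey, q)
            else:
                nsum = 1.0
                for c in nkey:
                    nsum *= float(q.q[q.categories.index(c)])
            nonf_cache[nkey] = nsum
        total += weight * func_cache[fkey] * nonf_cache[nkey]
    return total
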