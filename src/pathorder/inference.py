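"""Maximum-likelihood estimation of the step-probability matrix.

The rows of P live on the probability simplex; they are reparameterised with
a per-step softmax against a fixed reference category, so the optimisation is
unconstrained:

    p_{k,i}   = exp(omega_{k,i}) / (1 + sum_{i' != ref} exp(omega_{k,i'}))
    p_{k,ref} = 1               / (1 + sum_{i' != ref} exp(omega_{k,i'}))

The negative cohort log-likelihood is minimised with Nelder-Mead from several
restarts.  Passenger rates q are fixed beforehand by the plug-in estimator.
Profiles with identical counts and score multisets contribute identical
likelihood factors and are deduplicated with multiplicity weights; for speed
the evaluator precomputes, per unique profile, the split weights that do not
depend on P, so each objective evaluation reduces to one dynamic-programming
pass over a shared count lattice plus a matrix-vector product.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from functools import reduce
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .io import CategorySet, MutationRecord, PathwayDefinition, build_pair_dataset, regroup_atomic, regroup_overlapping
from .likelihood import (
    NonFunctionalRates,
    PatientProfile,
    StepProbabilities,
    _split_weight_tensor,
    cohort_log_likelihood,
    estimate_q,
    poisson_binomial_pmf,
)
from .ordering import OrderProbabilities, temporal_order_probabilities

__all__ = [
    "SoftmaxParams",
    "FitResult",
    "PairFit",
    "softmax_to_probs",
    "probs_to_softmax",
    "fit_mle",
    "fit_pairwise",
    "fit_joint",
    "k_stability_diagnostic",
]

DEFAULT_K = 4
DEFAULT_RESTARTS = 5
RESTART_SCALE = 0.5  # omega-space perturbation of restart starting points


@dataclass(frozen=True)
class SoftmaxParams:
    """Unconstrained omega matrix (K rows, one column per non-reference
    category; the reference category is the last of ``categories``)."""

    categories: tuple[str, ...]
    omega: np.ndarray

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        if omega.ndim != 2 or omega.shape[1] != len(self.categories) - 1:
            raise ValueError("omega must be (K, n_categories - 1)")
        if not np.all(np.isfinite(omega)):
            raise ValueError("omega entries must be finite")
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "omega", omega)

    @property
    def reference_category(self) -> str:
        return self.categories[-1]


def softmax_to_probs(params: SoftmaxParams) -> StepProbabilities:
    """Map omega rows onto simplex rows (overflow-guarded by max subtraction)."""
    z = np.concatenate(
        [params.omega, np.zeros((params.omega.shape[0], 1))], axis=1
    )
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    return StepProbabilities(params.categories, probs)


def probs_to_softmax(P: StepProbabilities) -> SoftmaxParams:
    """Inverse map omega_{k,i} = log(p_{k,i} / p_{k,ref}); boundary entries
    are clipped into (0, 1) with a warning."""
    probs = P.probs
    if np.any(probs <= 0) or np.any(probs >= 1):
        warnings.warn("probabilities at the simplex boundary clipped to [1e-8, 1-1e-8]")
        probs = np.clip(probs, 1e-8, 1 - 1e-8)
        probs = probs / probs.sum(axis=1, keepdims=True)
    omega = np.log(probs[:, :-1]) - np.log(probs[:, -1:])
    return SoftmaxParams(P.categories, omega)


@dataclass(frozen=True)
class FitResult:
    P_hat: StepProbabilities
    q: NonFunctionalRates
    loglik: float
    n_restarts: int
    converged: bool
    K: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "categories": list(self.P_hat.categories),
                "P": self.P_hat.probs.tolist(),
                "q": self.q.q.tolist(),
                "loglik": self.loglik,
                "K": self.K,
                "n_restarts": self.n_restarts,
                "converged": self.converged,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# fast cohort evaluator
# ---------------------------------------------------------------------------

class _CohortEvaluator:
    """Precomputed cohort log-likelihood as a function of P.

    For each unique profile the split weights
    w(n) = [prod_i PB_i(n_i)] * (m - sum n)! * prod_i q_i^{Y_i - n_i}/(Y_i - n_i)!
    are fixed once q is fixed; only the interleaving weights W(n) depend on P,
    and all needed W(n) live on one lattice shared by the whole cohort.
    """

    def __init__(
        self,
        profiles: Sequence[PatientProfile],
        categories: Sequence[str],
        q: NonFunctionalRates,
        sequence_multiplicity: bool = True,
    ) -> None:
        self.categories = tuple(categories)
        C = len(self.categories)
        # deduplicate profiles by (counts, rounded score multisets)
        groups: dict[tuple, int] = {}
        reps: dict[tuple, PatientProfile] = {}
        for prof in profiles:
            key = tuple(
                (c, prof.counts.get(c, 0),
                 tuple(round(r, 6) for r in prof.scores.get(c, ())))
                for c in self.categories
            )
            groups[key] = groups.get(key, 0) + 1
            reps.setdefault(key, prof)
        self.multiplicity = np.array([groups[k] for k in groups], dtype=float)
        uniques = [reps[k] for k in groups]

        dims = tuple(
            max(p.counts.get(c, 0) for p in uniques) + 1 for c in self.categories
        )
        self.dims = dims
        n_cells = int(np.prod(dims))
        strides = np.array(
            [int(np.prod(dims[i + 1:], dtype=int)) for i in range(C)], dtype=int
        )
        self.strides = strides
        grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
        coords = np.stack([g.ravel() for g in grids], axis=1)
        totals = coords.sum(axis=1)
        self.max_total = int(totals.max())
        # per total t and category i: child/parent flat-index pairs for the DP
        self.dp_steps: list[list[tuple[np.ndarray, np.ndarray]]] = []
        for t in range(1, self.max_total + 1):
            at_t = np.nonzero(totals == t)[0]
            per_cat = []
            for i in range(C):
                child = at_t[coords[at_t, i] > 0]
                per_cat.append((child, child - strides[i]))
            self.dp_steps.append(per_cat)
        self.n_cells = n_cells

        # split-weight matrix A: rows unique profiles, columns lattice cells
        A = np.zeros((len(uniques), n_cells))
        for row, prof in enumerate(uniques):
            Y = np.array([prof.counts.get(c, 0) for c in self.categories], dtype=int)
            pbs = [
                poisson_binomial_pmf(prof.scores.get(c, ()))
                for c in self.categories
            ]
            weight = _split_weight_tensor(Y, pbs, q, sequence_multiplicity).ravel()
            flat = reduce(
                np.add.outer, [np.arange(y + 1) * s for y, s in zip(Y, strides)]
            ).ravel()
            A[row, flat] = weight
        self.A = A

    def lattice_W(self, P: StepProbabilities) -> np.ndarray:
        rows = P.extended(max(self.max_total, 1))
        W = np.zeros(self.n_cells)
        W[0] = 1.0
        for t, per_cat in enumerate(self.dp_steps, start=1):
            row = rows[t - 1]
            for i, (child, parent) in enumerate(per_cat):
                if child.size:
                    W[child] += row[i] * W[parent]
        return W

    def log_likelihood(self, P: StepProbabilities) -> float:
        lik = self.A @ self.lattice_W(P)
        if np.any(lik <= 0.0):
            return float("-inf")
        return float(self.multiplicity @ np.log(lik))


def fit_mle(
    profiles: Sequence[PatientProfile],
    K: int = DEFAULT_K,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    categories: Sequence[str] | None = None,
    q: NonFunctionalRates | None = None,
    maxiter: int | None = None,
    sequence_multiplicity: bool = True,
) -> FitResult:
    """Maximise the cohort likelihood over P with q fixed by the plug-in
    estimator.  First start: uniform rows; remaining starts are seeded
    omega-space perturbations.  Deterministic given (inputs, seed)."""
    if not profiles:
        raise ValueError("no profiles to fit")
    if K < 1:
        raise ValueError("K must be >= 1")
    if categories is None:
        categories = sorted({c for p in profiles for c in p.counts})
    categories = tuple(categories)
    C = len(categories)
    if C < 2:
        raise ValueError("need at least two categories")
    if q is None:
        q = estimate_q(profiles, categories)
    evaluator = _CohortEvaluator(profiles, categories, q, sequence_multiplicity)
    dim = K * (C - 1)

    def objective(x: np.ndarray) -> float:
        P = softmax_to_probs(SoftmaxParams(categories, x.reshape(K, C - 1)))
        ll = evaluator.log_likelihood(P)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    starts = [np.zeros(dim)]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.normal(scale=RESTART_SCALE, size=dim))
    if all(objective(x0) >= 1e12 for x0 in starts):
        raise ValueError("objective non-finite at every starting point")

    best = None
    converged = False
    if maxiter is None:
        maxiter = 200 * dim
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    P_hat = softmax_to_probs(SoftmaxParams(categories, best.x.reshape(K, C - 1)))
    loglik = cohort_log_likelihood(profiles, P_hat, q, sequence_multiplicity)
    return FitResult(P_hat, q, loglik, len(starts), converged, K)


# ---------------------------------------------------------------------------
# pairwise / joint drivers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairFit:
    """One pathway pair's fit plus the dataset facts needed downstream."""

    pair: tuple[str, str]
    category_set: CategorySet
    fit: FitResult | None
    n_patients: int
    max_mutations: int
    skipped: bool = False

    def order_probabilities(self, require_both: bool = False) -> OrderProbabilities:
        if self.fit is None:
            raise ValueError(f"pair {self.pair} was skipped (no informative patients)")
        return temporal_order_probabilities(
            self.fit.P_hat,
            self.category_set,
            horizon=max(self.max_mutations, 1),
            require_both=require_both,
        )


def fit_pairwise(
    cohort: Mapping[str, Sequence[MutationRecord]],
    pathways: Sequence[PathwayDefinition],
    K: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    include_other: bool = False,
) -> dict[tuple[str, str], PairFit]:
    """Fit each of the C(N,2) pathway pairs separately (overlaps regrouped
    into A'/AB/B' categories).  Pairs without informative patients are
    flagged and skipped rather than raising."""
    if len(pathways) < 2:
        raise ValueError("need >= 2 pathways")
    fits: dict[tuple[str, str], PairFit] = {}
    for ai in range(len(pathways)):
        for bi in range(ai + 1, len(pathways)):
            pA, pB = pathways[ai], pathways[bi]
            cs = regroup_overlapping(pA, pB)
            profiles = build_pair_dataset(cohort, cs, include_other=include_other)
            pair = (pA.name, pB.name)
            if not profiles:
                fits[pair] = PairFit(pair, cs, None, 0, 0, skipped=True)
                continue
            categories = list(cs.categories) + (["other"] if include_other else [])
            fit = fit_mle(
                profiles, K=K, n_restarts=n_restarts, seed=seed, categories=categories
            )
            fits[pair] = PairFit(
                pair, cs, fit, len(profiles), max(p.total for p in profiles)
            )
    return fits


def fit_joint(
    cohort: Mapping[str, Sequence[MutationRecord]],
    pathways: Sequence[PathwayDefinition],
    K: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    max_states: int = 200_000,
) -> tuple[FitResult, CategorySet, list[PatientProfile]]:
    """Fit all pathways simultaneously over atomic intersection categories.

    The dynamic-programming state space is the product over categories of
    (max per-patient count + 1); inputs exceeding ``max_states`` are refused
    with a pointer to pairwise mode.
    """
    cs = regroup_atomic(pathways)
    profiles = build_pair_dataset(cohort, cs)
    if not profiles:
        raise ValueError("no patient carries a mutation in any pathway")
    state_size = 1
    for c in cs.categories:
        state_size *= max(p.counts.get(c, 0) for p in profiles) + 1
    if state_size > max_states:
        raise ValueError(
            f"joint DP state space {state_size} exceeds budget {max_states}; "
            "use pairwise mode"
        )
    fit = fit_mle(
        profiles, K=K, n_restarts=n_restarts, seed=seed, categories=cs.categories
    )
    return fit, cs, profiles


def k_stability_diagnostic(
    cohort: Mapping[str, Sequence[MutationRecord]],
    pathways: Sequence[PathwayDefinition],
    K_range: Sequence[int],
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
):
    """Order probabilities per pathway pair across truncation depths K, with
    adjacent-K absolute differences — the diagnostic used to pick K."""
    import pandas as pd

    K_range = list(K_range)
    if K_range != sorted(K_range):
        raise ValueError("K_range must be ascending")
    rows = []
    prev: dict[tuple[str, str], OrderProbabilities] = {}
    for K in K_range:
        fits = fit_pairwise(cohort, pathways, K=K, seed=seed, n_restarts=n_restarts)
        for pair, pf in fits.items():
            if pf.skipped:
                continue
            op = pf.order_probabilities()
            row = {
                "pair": f"{pair[0]}|{pair[1]}",
                "K": K,
                "p_before": op.p_before,
                "p_equal": op.p_equal,
                "p_after": op.p_after,
            }
            if pair in prev:
                prior = prev[pair]
                row["max_abs_diff_vs_prev_K"] = max(
                    abs(op.p_before - prior.p_before),
                    abs(op.p_equal - prior.p_equal),
                    abs(op.p_after - prior.p_after),
                )
            prev[pair] = op
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(K_range) == 1 and "max_abs_diff_vs_prev_K" in table.columns:
        table = table.drop(columns=["max_abs_diff_vs_prev_K"])
    return table
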