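"""Temporal-order probabilities of pathway pairs from a fitted step matrix.

P(A<B) is the probability, under the sequence law prod_k p_{k,i_k}, that the
first functional mutation altering pathway A occurs strictly before the first
one altering B; P(A=B) that the first relevant event hits a shared-gene
category (altering both at once); P(A>B) the reverse.  Computed exactly by a
forward pass with absorption at the first classifying event — no sequence
enumeration — over a horizon of n steps (the pipeline uses the maximum
per-patient mutation count).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CategorySet
from .likelihood import PatientProfile, StepProbabilities, poisson_binomial_pmf

__all__ = [
    "OrderProbabilities",
    "classify_sequence",
    "temporal_order_probabilities",
    "enumerate_order_probabilities",
    "functional_count_distribution",
    "order_probability_matrix",
]


@dataclass(frozen=True)
class OrderProbabilities:
    """P(A<B), P(A=B), P(A>B) and the mass left unclassified at the horizon."""

    pair: tuple[str, str]
    p_before: float
    p_equal: float
    p_after: float
    p_undetermined: float
    horizon: int

    def __post_init__(self) -> None:
        vals = (self.p_before, self.p_equal, self.p_after, self.p_undetermined)
        if any(not (-1e-12 <= v <= 1 + 1e-12) for v in vals):
            raise ValueError("order probabilities must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-10:
            raise ValueError("order probabilities must sum to 1")


def _alter_sets(
    cs: CategorySet, a: str | None, b: str | None
) -> tuple[str, str, dict[str, str]]:
    if a is None or b is None:
        if len(cs.pathways) != 2:
            raise ValueError("pathway pair (a, b) required for non-pair category sets")
        a, b = cs.pathways
    kind = {}
    for label in cs.categories:
        alt = cs.alters.get(label, frozenset())
        hits_a, hits_b = a in alt, b in alt
        if hits_a and hits_b:
            kind[label] = "both"
        elif hits_a:
            kind[label] = "a"
        elif hits_b:
            kind[label] = "b"
        else:
            kind[label] = "none"
    return a, b, kind


def classify_sequence(
    seq: Sequence[str], cs: CategorySet, a: str | None = None, b: str | None = None
) -> str:
    """Classify a functional-category sequence as A_first / B_first /
    simultaneous / undetermined by the first event touching each pathway.

    A pathway never altered counts as altered at infinity, so a sequence
    touching only A is A_first.
    """
    a, b, kind = _alter_sets(cs, a, b)
    t_a = t_b = None
    for t, label in enumerate(seq):
        if label not in kind:
            raise ValueError(f"unknown category label {label!r}")
        k = kind[label]
        if k in ("a", "both") and t_a is None:
            t_a = t
        if k in ("b", "both") and t_b is None:
            t_b = t
        if t_a is not None and t_b is not None:
            break
    if t_a is None and t_b is None:
        return "undetermined"
    if t_a is not None and (t_b is None or t_a < t_b):
        return "A_first"
    if t_b is not None and (t_a is None or t_b < t_a):
        return "B_first"
    return "simultaneous"


def temporal_order_probabilities(
    P: StepProbabilities,
    cs: CategorySet,
    horizon: int,
    a: str | None = None,
    b: str | None = None,
    require_both: bool = False,
) -> OrderProbabilities:
    """Exact class probabilities under the sequence law, by a forward pass.

    With the default convention a sequence is classified at the first event
    altering either pathway (a pathway never altered within the horizon counts
    as later); ``require_both`` instead demands both pathways be altered
    within the horizon, moving one-sided mass to undetermined.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    a, b, kind = _alter_sets(cs, a, b)
    if tuple(P.categories) != tuple(cs.categories):
        raise ValueError("P categories must match the category set")
    idx_a = [i for i, c in enumerate(cs.categories) if kind[c] == "a"]
    idx_b = [i for i, c in enumerate(cs.categories) if kind[c] == "b"]
    idx_ab = [i for i, c in enumerate(cs.categories) if kind[c] == "both"]
    idx_none = [i for i, c in enumerate(cs.categories) if kind[c] == "none"]

    p_before = p_equal = p_after = 0.0
    if not require_both:
        u = 1.0
        for k in range(1, horizon + 1):
            row = P.row(k)
            p_before += u * float(row[idx_a].sum())
            p_after += u * float(row[idx_b].sum())
            p_equal += u * float(row[idx_ab].sum())
            u *= float(row[idx_none].sum())
        undet = u
    else:
        u_none, u_a, u_b = 1.0, 0.0, 0.0
        for k in range(1, horizon + 1):
            row = P.row(k)
            sa = float(row[idx_a].sum())
            sb = float(row[idx_b].sum())
            sab = float(row[idx_ab].sum())
            s0 = float(row[idx_none].sum())
            p_equal += u_none * sab
            p_before += u_a * (sb + sab)
            p_after += u_b * (sa + sab)
            u_a, u_b, u_none = (
                u_a * (sa + s0) + u_none * sa,
                u_b * (sb + s0) + u_none * sb,
                u_none * s0,
            )
        undet = u_none + u_a + u_b
    return OrderProbabilities((a, b), p_before, p_equal, p_after, undet, horizon)


def enumerate_order_probabilities(
    P: StepProbabilities,
    cs: CategorySet,
    horizon: int,
    a: str | None = None,
    b: str | None = None,
) -> OrderProbabilities:
    """Brute-force oracle: classify every one of the C^horizon sequences and
    sum its probability prod_k p_{k, i_k}.  Exponential; for validation only."""
    a, b, _ = _alter_sets(cs, a, b)
    rows = P.extended(horizon)
    acc = {"A_first": 0.0, "B_first": 0.0, "simultaneous": 0.0, "undetermined": 0.0}
    cats = cs.categories
    for seq in product(range(len(cats)), repeat=horizon):
        prob = 1.0
        for k, i in enumerate(seq):
            prob *= rows[k, i]
        acc[classify_sequence([cats[i] for i in seq], cs, a, b)] += prob
    return OrderProbabilities(
        (a, b), acc["A_first"], acc["simultaneous"], acc["B_first"],
        acc["undetermined"], horizon,
    )


def functional_count_distribution(
    profiles: Sequence[PatientProfile], horizon: int
) -> np.ndarray:
    """Cohort-level distribution of the number of functional mutations.

    Average over patients of the Poisson-binomial pmf of all their in-pair
    impact scores, padded to the horizon; used as the diagnostic supporting a
    choice of truncation depth K.
    """
    length = horizon + 1
    pmfs = []
    for prof in profiles:
        pmf = poisson_binomial_pmf(prof.all_scores())
        length = max(length, len(pmf))
        pmfs.append(pmf)
    if not pmfs:
        return np.zeros(length)
    out = np.zeros(length)
    for pmf in pmfs:
        out[: len(pmf)] += pmf
    return out / len(pmfs)


def order_probability_matrix(pair_fits: Mapping) -> pd.DataFrame:
    """Square table of P(row pathway altered before column pathway).

    ``pair_fits`` maps unordered pathway pairs to PairFit results (from
    ``fit_pairwise``); each pair's horizon is its dataset's maximum
    per-patient mutation count.  Skipped pairs are left NaN, as is the
    diagonal.
    """
    names = sorted({name for pair in pair_fits for name in pair})
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for pair, pf in pair_fits.items():
        if pf.skipped:
            continue
        op = pf.order_probabilities()
        a, b = op.pair
        mat.loc[a, b] = op.p_before
        mat.loc[b, a] = op.p_after
    return mat


def collect_order_probabilities(pair_fits: Mapping) -> dict[frozenset, OrderProbabilities]:
    """Map each fitted pair to its OrderProbabilities (skipped pairs omitted)."""
    out = {}
    for pair, pf in pair_fits.items():
        if not pf.skipped:
            out[frozenset(pair)] = pf.order_probabilities()
    return out
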