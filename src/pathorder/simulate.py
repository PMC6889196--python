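"""Synthetic cohorts with the generative structure of the pairwise model.

Per patient, four steps: (1) draw the numbers of functional and non-functional
mutations from configurable count distributions; (2) assign the k-th
functional mutation to category i with probability p_{k,i} (truncated step
matrix reused beyond depth K); (3) assign non-functional mutations to
categories with probabilities q_i; (4) draw each mutation's functional-impact
score from the arm of the score model matching its hidden functional status.
The hidden indicators and sequence are retained for evaluation but withheld
from the profiles handed to inference.

Also provides the score-perturbation experiment (shift all scores of one
category and watch the estimated order probabilities move) and the bias
harness (mean absolute error of the estimated order probabilities across
replicates and sample sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CategorySet, MutationRecord, PathwayDefinition
from .inference import fit_mle
from .likelihood import NonFunctionalRates, PatientProfile, StepProbabilities
from .ordering import OrderProbabilities, temporal_order_probabilities

__all__ = [
    "ScoreModel",
    "SimulationConfig",
    "default_config",
    "default_pair_category_set",
    "truncated_poisson_pmf",
    "simulate_cohort",
    "cohort_to_records",
    "perturb_scores",
    "evaluate_bias",
    "truth_order_probabilities",
]


@dataclass(frozen=True)
class ScoreModel:
    """Beta-distributed impact scores, one arm per hidden functional status.

    The default arms are *calibrated*: they are the conditional score
    distributions implied by drawing a score ``r`` from a base Beta(a, b) and
    letting the mutation be functional with probability ``r`` — functional
    scores follow Beta(a+1, b) and passenger scores Beta(a, b+1).  Under
    calibration the score really is the probability the mutation is
    functional, which is what the likelihood assumes, so the estimator is
    consistent.  The base mean a/(a+b) must match the generator's functional
    mutation fraction (1/3 under the default count distributions); the
    default base Beta(0.02, 0.04) reproduces the strongly bimodal shape of
    real PolyPhen-2 annotations, whose scores pile up at 0 and 1 with
    class-conditional means near 0.96 (damaging) and 0.02 (benign).
    Arbitrary (uncalibrated) arms may be supplied for sensitivity experiments.
    """

    functional: tuple[float, float] = (1.02, 0.04)
    nonfunctional: tuple[float, float] = (0.02, 1.04)

    @classmethod
    def calibrated(cls, a: float, b: float) -> "ScoreModel":
        """Arms implied by base score distribution Beta(a, b) with the
        mutation functional with probability equal to its score."""
        return cls(functional=(a + 1.0, b), nonfunctional=(a, b + 1.0))

    def draw(self, rng: np.random.Generator, functional: bool) -> float:
        a, b = self.functional if functional else self.nonfunctional
        return float(rng.beta(a, b))


def truncated_poisson_pmf(lam: float, max_k: int) -> np.ndarray:
    """Poisson(lam) pmf truncated (and renormalised) to 0..max_k."""
    k = np.arange(max_k + 1)
    logpmf = k * np.log(lam) - lam - np.array(
        [float(np.sum(np.log(np.arange(1, kk + 1)))) for kk in k]
    )
    pmf = np.exp(logpmf)
    return pmf / pmf.sum()


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    truth_P: StepProbabilities
    truth_q: NonFunctionalRates
    functional_count_dist: np.ndarray
    nonfunctional_count_dist: np.ndarray
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("functional_count_dist", "nonfunctional_count_dist"):
            pmf = np.asarray(getattr(self, name), dtype=float)
            if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a pmf summing to 1")
            object.__setattr__(self, name, pmf)
        if tuple(self.truth_P.categories) != tuple(self.truth_q.categories):
            raise ValueError("truth_P and truth_q categories differ")


# Default study conditions: a pair of overlapping pathways (categories A', AB,
# B'), pathway A clearly favoured as the first altered (P(A<B) = 0.7), a small
# shared-gene category carrying the simultaneous-alteration mass, and mutation
# loads typical of non-hypermutated exomes (about 1.5 expected functional and
# 3 expected passenger in-pair mutations per patient).
_DEFAULT_CATEGORIES = ("A'", "AB", "B'")
_DEFAULT_P = np.array(
    [
        [0.70, 0.10, 0.20],
        [0.50, 0.10, 0.40],
        [0.40, 0.10, 0.50],
        [0.35, 0.10, 0.55],
    ]
)
_DEFAULT_Q = np.array([0.45, 0.10, 0.45])


def default_pair_category_set() -> CategorySet:
    """Category set of the default simulated pathway pair, with synthetic
    gene pools per category."""
    genes = {
        "A'": frozenset(f"GA{i:02d}" for i in range(8)),
        "AB": frozenset(f"GS{i:02d}" for i in range(3)),
        "B'": frozenset(f"GB{i:02d}" for i in range(12)),
    }
    alters = {"A'": frozenset({"A"}), "AB": frozenset({"A", "B"}), "B'": frozenset({"B"})}
    return CategorySet(_DEFAULT_CATEGORIES, genes, alters, ("A", "B"))


def default_config(n_patients: int = 400, seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        n_patients=n_patients,
        truth_P=StepProbabilities(_DEFAULT_CATEGORIES, _DEFAULT_P),
        truth_q=NonFunctionalRates(_DEFAULT_CATEGORIES, _DEFAULT_Q),
        functional_count_dist=truncated_poisson_pmf(1.5, 6),
        nonfunctional_count_dist=truncated_poisson_pmf(3.0, 15),
        seed=seed,
    )


def disjoint_category_set(names: Sequence[str], genes_per: int = 6) -> CategorySet:
    """Category set for disjoint pathways (one category per pathway), with
    synthetic gene pools — convenient for multi-pathway simulations."""
    genes = {
        name: frozenset(f"G{name}{i:02d}" for i in range(genes_per)) for name in names
    }
    alters = {name: frozenset({name}) for name in names}
    return CategorySet(tuple(names), genes, alters, tuple(names))


@dataclass(frozen=True)
class PatientTruth:
    sample_id: str
    functional_sequence: tuple[str, ...]
    nonfunctional_labels: tuple[str, ...]


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[PatientProfile], list[PatientTruth]]:
    """Generate one cohort; deterministic given ``cfg.seed``.

    Patients with zero total mutations carry no likelihood information and
    are excluded from the returned profiles (their truth records are kept).
    """
    rng = np.random.default_rng(cfg.seed)
    cats = cfg.truth_P.categories
    n_cat = len(cats)
    profiles: list[PatientProfile] = []
    truths: list[PatientTruth] = []
    f_support = np.arange(len(cfg.functional_count_dist))
    nf_support = np.arange(len(cfg.nonfunctional_count_dist))
    for j in range(cfg.n_patients):
        sample = f"SIM{j:05d}"
        n_func = int(rng.choice(f_support, p=cfg.functional_count_dist))
        n_nonf = int(rng.choice(nf_support, p=cfg.nonfunctional_count_dist))
        func_seq = tuple(
            cats[int(rng.choice(n_cat, p=cfg.truth_P.row(k)))]
            for k in range(1, n_func + 1)
        )
        nonf_labels = tuple(
            cats[int(rng.choice(n_cat, p=cfg.truth_q.q))] for _ in range(n_nonf)
        )
        truths.append(PatientTruth(sample, func_seq, nonf_labels))
        scores: dict[str, list[float]] = {c: [] for c in cats}
        for label in func_seq:
            scores[label].append(cfg.score_model.draw(rng, functional=True))
        for label in nonf_labels:
            scores[label].append(cfg.score_model.draw(rng, functional=False))
        counts = {c: len(v) for c, v in scores.items()}
        if sum(counts.values()) == 0:
            continue
        profiles.append(
            PatientProfile(sample, counts, {c: tuple(v) for c, v in scores.items()})
        )
    return profiles, truths


def cohort_to_records(
    profiles: Sequence[PatientProfile],
    cs: CategorySet,
    seed: int = 0,
) -> dict[str, list[MutationRecord]]:
    """Render simulated profiles as MAF-style records, drawing each mutation's
    gene uniformly from its category's synthetic gene pool."""
    rng = np.random.default_rng(seed)
    cohort: dict[str, list[MutationRecord]] = {}
    for prof in profiles:
        recs = []
        for c in cs.categories:
            pool = sorted(cs.category_genes[c])
            for r in prof.scores.get(c, ()):
                gene = pool[int(rng.integers(len(pool)))]
                recs.append(MutationRecord(prof.sample_id, gene, "missense", r))
        cohort[prof.sample_id] = recs
    return cohort


def perturb_scores(
    profiles: Sequence[PatientProfile], category: str, delta: float
) -> list[PatientProfile]:
    """Shift every impact score in one category by ``delta``, clipped to
    [0, 1]; other categories untouched."""
    out = []
    for prof in profiles:
        scores = dict(prof.scores)
        if category in scores:
            scores[category] = tuple(
                min(1.0, max(0.0, r + delta)) for r in scores[category]
            )
        out.append(PatientProfile(prof.sample_id, dict(prof.counts), scores))
    return out


def truth_order_probabilities(cfg: SimulationConfig, cs: CategorySet) -> OrderProbabilities:
    """Order probabilities implied by the truth step matrix (the bias metric's
    reference point — computed, not set independently)."""
    horizon = (
        len(cfg.functional_count_dist) + len(cfg.nonfunctional_count_dist)
    )
    return temporal_order_probabilities(cfg.truth_P, cs, horizon=horizon)


def evaluate_bias(
    cfg: SimulationConfig,
    n_replicates: int,
    sample_sizes: Sequence[int],
    K: int | None = None,
    n_restarts: int = 5,
    cs: CategorySet | None = None,
) -> pd.DataFrame:
    """Mean absolute error of estimated order probabilities vs truth.

    For each sample size, ``n_replicates`` cohorts are simulated (seeds split
    deterministically from ``cfg.seed``), fitted, and converted to order
    probabilities; the table reports the mean |estimate - truth| per quantity.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if cs is None:
        cs = default_pair_category_set()
    if K is None:
        K = cfg.truth_P.K
    truth = truth_order_probabilities(cfg, cs)
    rows = []
    for size in sample_sizes:
        errs = np.zeros(3)
        for rep in range(n_replicates):
            child_seed = int(
                np.random.SeedSequence([cfg.seed, int(size), rep]).generate_state(1)[0]
                % (2**31)
            )
            rep_cfg = replace(cfg, n_patients=int(size), seed=child_seed)
            profiles, _ = simulate_cohort(rep_cfg)
            fit = fit_mle(
                profiles,
                K=K,
                n_restarts=n_restarts,
                seed=child_seed,
                categories=cfg.truth_P.categories,
            )
            horizon = max(p.total for p in profiles)
            est = temporal_order_probabilities(fit.P_hat, cs, horizon=horizon)
            errs += np.abs(
                np.array([est.p_before, est.p_equal, est.p_after])
                - np.array([truth.p_before, truth.p_equal, truth.p_after])
            )
        errs /= n_replicates
        rows.append(
            {
                "sample_size": int(size),
                "bias_p_before": errs[0],
                "bias_p_equal": errs[1],
                "bias_p_after": errs[2],
            }
        )
    return pd.DataFrame(rows).set_index("sample_size")
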