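import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathorder import (
    NonFunctionalRates,
    PatientProfile,
    StepProbabilities,
    brute_force_likelihood,
    cohort_log_likelihood,
    estimate_q,
    interleaving_weight,
    nonfunctional_weight,
    patient_likelihood,
    poisson_binomial_pmf,
)
from conftest import random_profile, random_rates, random_step_probs


class TestPoissonBinomial:
    def test_certain_success(self):
        assert poisson_binomial_pmf([1.0]) == pytest.approx([0.0, 1.0])

    def test_symmetric_pair(self):
        assert poisson_binomial_pmf([0.5, 0.5]) == pytest.approx([0.25, 0.5, 0.25])

    def test_matches_subset_enumeration(self):
        scores = [0.98, 0.2, 0.7]
        expected = np.zeros(4)
        for flags in itertools.product([0, 1], repeat=3):
            w = math.prod(r if f else 1 - r for f, r in zip(flags, scores))
            expected[sum(flags)] += w
        assert poisson_binomial_pmf(scores) == pytest.approx(list(expected))

    @given(st.lists(st.floats(0, 1), min_size=0, max_size=12))
    @settings(derandomize=True, max_examples=50)
    def test_sums_to_one(self, scores):
        assert poisson_binomial_pmf(scores).sum() == pytest.approx(1.0, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            poisson_binomial_pmf([1.2])


class TestInterleavingWeight:
    def test_single_sequence(self, rng):
        P = random_step_probs(rng)
        assert interleaving_weight({"A'": 1}, P) == pytest.approx(P.probs[0, 0])

    def test_two_interleavings(self, rng):
        P = random_step_probs(rng)
        expected = (
            P.probs[0, 0] * P.probs[1, 2] + P.probs[0, 2] * P.probs[1, 0]
        )
        assert interleaving_weight({"A'": 1, "B'": 1}, P) == pytest.approx(expected)

    def test_matches_sequence_enumeration(self, rng):
        P = random_step_probs(rng, categories=("A'", "B'"), K=4)
        counts = {"A'": 2, "B'": 2}
        total = 0.0
        for seq in set(itertools.permutations(["A'"] * 2 + ["B'"] * 2)):
            rows = P.extended(4)
            total += math.prod(
                rows[k, 0 if c == "A'" else 1] for k, c in enumerate(seq)
            )
        assert interleaving_weight(counts, P) == pytest.approx(total)

    def test_truncation_reuses_last_row(self, rng):
        # with 6 events and K=4, steps 5-6 use row 4
        P = random_step_probs(rng, categories=("A'", "B'"), K=4)
        w = interleaving_weight({"A'": 6}, P)
        rows = P.extended(6)
        assert w == pytest.approx(math.prod(rows[k, 0] for k in range(6)))

    def test_total_probability_over_splits(self, rng):
        P = random_step_probs(rng)
        n = 4
        total = 0.0
        for na in range(n + 1):
            for nb in range(n - na + 1):
                counts = {"A'": na, "AB": nb, "B'": n - na - nb}
                total += interleaving_weight(counts, P)
        assert total == pytest.approx(1.0, abs=1e-10)


class TestNonFunctionalWeight:
    def test_single(self):
        q = NonFunctionalRates(("A'", "B'"), np.array([0.3, 0.7]))
        assert nonfunctional_weight({"A'": 1}, q) == pytest.approx(0.3)

    def test_two_arrangements(self):
        q = NonFunctionalRates(("A'", "B'"), np.array([0.3, 0.7]))
        assert nonfunctional_weight({"A'": 1, "B'": 1}, q) == pytest.approx(0.42)

    def test_three_sequences(self):
        q = NonFunctionalRates(("A'", "B'"), np.array([0.5, 0.5]))
        assert nonfunctional_weight({"A'": 2, "B'": 1}, q) == pytest.approx(0.375)

    def test_total_probability_over_splits(self, rng):
        q = random_rates(rng)
        n = 5
        total = sum(
            nonfunctional_weight({"A'": na, "AB": nb, "B'": n - na - nb}, q)
            for na in range(n + 1)
            for nb in range(n - na + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestPatientLikelihood:
    def test_single_certain_functional(self, rng):
        P = random_step_probs(rng)
        q = random_rates(rng)
        prof = PatientProfile("s", {"A'": 1}, {"A'": (1.0,)})
        assert patient_likelihood(prof, P, q) == pytest.approx(P.probs[0, 0])

    def test_single_uncertain_mutation_mixes_two_latent_states(self, rng):
        P = random_step_probs(rng)
        q = random_rates(rng)
        prof = PatientProfile("s", {"A'": 1}, {"A'": (0.3,)})
        expected = 0.3 * P.probs[0, 0] + 0.7 * q.q[0]
        assert patient_likelihood(prof, P, q) == pytest.approx(expected)

    @pytest.mark.parametrize("sequence_multiplicity", [True, False])
    def test_matches_brute_force(self, rng, sequence_multiplicity):
        for _ in range(60):
            P = random_step_probs(rng)
            q = random_rates(rng)
            prof = random_profile(rng, max_total=6)
            fast = patient_likelihood(prof, P, q, sequence_multiplicity)
            slow = brute_force_likelihood(prof, P, q, sequence_multiplicity)
            assert fast == pytest.approx(slow, rel=1e-9)

    def test_invariant_to_score_order_within_category(self, rng):
        P = random_step_probs(rng)
        q = random_rates(rng)
        a = PatientProfile("s", {"A'": 3}, {"A'": (0.9, 0.2, 0.5)})
        b = PatientProfile("s", {"A'": 3}, {"A'": (0.5, 0.9, 0.2)})
        assert patient_likelihood(a, P, q) == patient_likelihood(b, P, q)

    def test_all_functional_reduces_to_pure_order_model(self, rng):
        P = random_step_probs(rng)
        q = random_rates(rng)
        prof = PatientProfile(
            "s", {"A'": 2, "B'": 1}, {"A'": (1.0, 1.0), "B'": (1.0,)}
        )
        assert patient_likelihood(prof, P, q) == pytest.approx(
            interleaving_weight({"A'": 2, "B'": 1}, P)
        )

    def test_all_passenger_reduces_to_multinomial_model(self, rng):
        P = random_step_probs(rng)
        q = random_rates(rng)
        prof = PatientProfile(
            "s", {"A'": 2, "B'": 1}, {"A'": (0.0, 0.0), "B'": (0.0,)}
        )
        assert patient_likelihood(prof, P, q) == pytest.approx(
            nonfunctional_weight({"A'": 2, "B'": 1}, q)
        )

    def test_brute_force_refuses_large_profiles(self, rng):
        P = random_step_probs(rng)
        q = random_rates(rng)
        prof = PatientProfile("s", {"A'": 9}, {"A'": tuple([0.5] * 9)})
        with pytest.raises(ValueError, match="at most 8"):
            brute_force_likelihood(prof, P, q)


class TestCohortLogLikelihood:
    def test_duplicated_patient_doubles_loglik(self, rng):
        P = random_step_probs(rng)
        q = random_rates(rng)
        prof = random_profile(rng)
        single = cohort_log_likelihood([prof], P, q)
        double = cohort_log_likelihood([prof, prof], P, q)
        assert double == pytest.approx(2 * single)

    def test_matches_per_patient_oracle_logs(self, rng):
        P = random_step_probs(rng)
        q = random_rates(rng)
        profiles = [random_profile(rng, max_total=5) for _ in range(20)]
        expected = sum(
            math.log(brute_force_likelihood(p, P, q)) for p in profiles
        )
        assert cohort_log_likelihood(profiles, P, q) == pytest.approx(expected)


class TestEstimateQ:
    def test_expected_passenger_mass_pooled(self):
        p1 = PatientProfile("p1", {"A'": 1, "B'": 0}, {"A'": (0.9,)})
        p2 = PatientProfile("p2", {"A'": 0, "B'": 1}, {"B'": (0.4,)})
        q = estimate_q([p1, p2], ("A'", "B'"))
        assert q.q[0] == pytest.approx(0.1 / 0.7)
        assert q.per_patient_expected["p1"]["A'"] == pytest.approx(0.1)

    def test_zero_scores_reduce_to_count_ratio(self):
        profs = [
            PatientProfile("p", {"A'": 3, "B'": 1}, {"A'": (0.0,) * 3, "B'": (0.0,)})
        ]
        q = estimate_q(profs, ("A'", "B'"))
        assert list(q.q) == pytest.approx([0.75, 0.25])

    def test_single_mutation_normalizes_to_one(self):
        profs = [PatientProfile("p", {"A'": 1}, {"A'": (0.2,)})]
        q = estimate_q(profs, ("A'",))
        assert q.q[0] == pytest.approx(1.0)

    def test_all_certain_scores_fall_back_to_uniform(self):
        profs = [PatientProfile("p", {"A'": 1, "B'": 1}, {"A'": (1.0,), "B'": (1.0,)})]
        with pytest.warns(UserWarning, match="uniform"):
            q = estimate_q(profs, ("A'", "B'"))
        assert list(q.q) == pytest.approx([0.5, 0.5])
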