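import numpy as np
import pytest

from pathorder import (
    NonFunctionalRates,
    PatientProfile,
    StepProbabilities,
)

CATS = ("A'", "AB", "B'")


def random_step_probs(rng, categories=CATS, K=4):
    return StepProbabilities(categories, rng.dirichlet(np.ones(len(categories)), size=K))


def random_rates(rng, categories=CATS):
    return NonFunctionalRates(categories, rng.dirichlet(np.ones(len(categories))))


def random_profile(rng, categories=CATS, max_total=6, min_total=1):
    total = int(rng.integers(min_total, max_total + 1))
    counts = dict.fromkeys(categories, 0)
    scores = {c: [] for c in categories}
    for _ in range(total):
        c = categories[int(rng.integers(len(categories)))]
        counts[c] += 1
        scores[c].append(float(rng.random()))
    return PatientProfile(
        f"R{rng.integers(1 << 30)}", counts, {c: tuple(v) for c, v in scores.items()}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_maf(tmp_path):
    """Five samples, genes from two overlapping pathways plus one stray gene."""
    rows = [
        "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tPolyPhen",
        "APC\tS1\tMissense_Mutation\tprobably_damaging(0.98)",
        "TP53\tS1\tNonsense_Mutation\t",
        "APC\tS2\tSilent\tbenign(0.01)",
        "CTNNB1\tS2\tMissense_Mutation\tbenign(0.05)",
        "TP53\tS3\tMissense_Mutation\t0.91",
        "KRAS\tS3\tMissense_Mutation\tpossibly_damaging(0.62)",
        "BRAF\tS4\tMissense_Mutation\t",
        "GREM1\tS4\tMissense_Mutation\tbenign(0.02)",
        "APC\tS5\tFrame_Shift_Del\t",
        "TP53\tS5\tMissense_Mutation\tprobably_damaging(0.99)",
    ]
    path = tmp_path / "toy.maf"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def toy_gmt(tmp_path):
    path = tmp_path / "toy.gmt"
    path.write_text(
        "WNT\tna\tAPC\tCTNNB1\tTP53\n"
        "MAPK\tna\tKRAS\tBRAF\tTP53\n"
    )
    return path
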