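import numpy as np
import pytest

from coevspec import (
    GroundTruthSpec,
    PottsModel,
    SpecificityModel,
    SpecificityScorer,
    make_ensemble,
)
from coevspec.alphabet import Alphabet


def random_potts(rng, L, q, provenance="canonical"):
    """Random Potts model in the gap gauge (symmetric, zero diagonal blocks)."""
    e = rng.normal(0.0, 0.5, (L, L, q, q))
    e[:, :, -1, :] = 0.0
    e[:, :, :, -1] = 0.0
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))
    idx = np.arange(L)
    e[idx, idx] = 0.0
    h = rng.normal(0.0, 0.5, (L, q))
    h[:, -1] = 0.0
    return PottsModel(e, h, Alphabet.reduced(q), provenance=provenance)


def random_specificity_model(seed=0, l_protease=4, l_substrate=5, q=4,
                             motif_window=(2, 4)):
    rng = np.random.default_rng(seed)
    return SpecificityModel(
        canonical=random_potts(rng, l_protease + l_substrate, q, "canonical"),
        scrambled=random_potts(rng, l_protease + l_substrate, q, "scrambled"),
        l_protease=l_protease,
        l_substrate=l_substrate,
        motif_window=motif_window,
    )


def random_sequences(rng, model, n=1, gapless=False):
    """Random aligned (protease, substrate) string pairs for a model."""
    letters = model.alphabet.letters[:-1] if gapless else model.alphabet.letters
    out = []
    for _ in range(n):
        p = "".join(rng.choice(list(letters), model.l_protease))
        s = "".join(rng.choice(list(letters), model.l_substrate))
        out.append((p, s))
    return out


@pytest.fixture(scope="session")
def small_ensemble():
    spec = GroundTruthSpec(
        l_protease=8, l_substrate=7, q=5, n_classes=2,
        coupled_pairs=((1, 2), (4, 5), (8, 7)), seed=3,
    )
    return make_ensemble(spec, n_rows=400, burn_in=50)


@pytest.fixture(scope="session")
def small_scorer(small_ensemble):
    return SpecificityScorer(scramble_seed=1).fit(small_ensemble.alignment)


@pytest.fixture(scope="session")
def default_recovery():
    """Full-scale planted-specificity recovery run (default generator spec)."""
    from coevspec import recovery_report

    ens = make_ensemble(GroundTruthSpec(), n_rows=5000, burn_in=200)
    scorer = SpecificityScorer(scramble_seed=1).fit(ens.alignment)
    report = recovery_report(ens, scorer, n_eval=100, n_mutation_trials=60,
                             rng_seed=1)
    return ens, scorer, report
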