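import pytest

from ppredit.code_scoring import AlignmentObservation, build_scoring_tables
from ppredit.ppr_model import AminoAcidPair


def worked_observations():
    """Hand-computable 5-pair training fixture (motif type P).

    Four pairs are each seen 40 times with a single base; the fifth is
    seen 10 times with each base.  Every row total is 40, every column
    total 50, grand total 200, so the independence expectation is 10 in
    every cell.  With pseudocount 10 the scores are therefore
    ln(50/20) where observed = 40, ln(10/20) where observed = 0, and
    exactly 0 for the balanced pair (observed = expected = 10).
    """
    pairs = [("T", "N"), ("T", "D"), ("S", "N"), ("S", "D"), ("N", "S")]
    obs = []
    for pair, base in zip(pairs[:4], ("A", "C", "G", "U")):
        obs.append(
            AlignmentObservation("P", AminoAcidPair(*pair), base, weight=40.0)
        )
    for base in "ACGU":
        obs.append(
            AlignmentObservation("P", AminoAcidPair(*pairs[4]), base, weight=10.0)
        )
    return pairs, obs
from ppredit.synthetic_data import (
    GeneratorConfig,
    simulate_protein_with_target,
    simulate_training_observations,
)


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def training(config):
    """(observations, planted-preference truth map) for the session config."""
    return simulate_training_observations(config)


@pytest.fixture(scope="session")
def tables(training):
    observations, _ = training
    return build_scoring_tables(observations)


@pytest.fixture(scope="session")
def planted(config, training):
    """(planted factor, target site, decoy proteins)."""
    _, truth = training
    return simulate_protein_with_target(config, truth)
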