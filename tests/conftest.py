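import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from tandemscan.align import AlignParams
from tandemscan.scoring import score_genome
from tandemscan.synthesis import (ArrayPlan, MinisatPairPlan, RelicPlan,
                                  SynthConfig, generate_genome)


@pytest.fixture(scope="session")
def params():
    return AlignParams()


@pytest.fixture(scope="session")
def planted():
    """Small genome with planted arrays covering the main structure types:
    a plain pair, a spacer triple, a convergent pair and a CDS+relic."""
    cfg = SynthConfig(seed=5, n_background=20, arrays=[
        ArrayPlan(size=2, identity=95),
        ArrayPlan(size=3, identity=85, spacers=(1,)),
        ArrayPlan(size=2, identity=88, orientations=("+", "-")),
        ArrayPlan(size=1, identity=100, relic=RelicPlan(position="end")),
    ])
    genome, truth = generate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def planted_scores(planted, params):
    _, genome, _ = planted
    return score_genome(genome, params)


@pytest.fixture(scope="session")
def minisat_world(params):
    """Genome with a paralog pair sharing a short internal repeat (a true
    array) and two unrelated neighbours sharing a long repeat (a fake one)."""
    cfg = SynthConfig(seed=11, n_background=12, arrays=[
        ArrayPlan(size=2, identity=92, minisat=(12, 4)),
    ], minisat_pairs=[MinisatPairPlan(unit_size=30, copies=14)])
    genome, truth = generate_genome(cfg)
    scores = score_genome(genome, params)
    return cfg, genome, truth, scores
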