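import numpy as np
import pytest

from seedbank import QuadratCounts, SimulationDesign, generate_dataset, load_occurrence_fixture


def make_quadrat(counts, site="S1", mode="RG", field=1, quadrat=1, **kw):
    return QuadratCounts(
        site_id=site, mode=mode, field_id=field, quadrat_id=quadrat, counts=dict(counts), **kw
    )


@pytest.fixture(scope="session")
def guild_map():
    _, pool = load_occurrence_fixture()
    return {s.species_id: s.guild for s in pool}


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset (12 sites, 36 fields)."""
    design = SimulationDesign(rng_seed=20200901)
    quadrats, practices, truth = generate_dataset(design)
    return design, quadrats, practices, truth


def random_small_survey(rng, max_quadrats=5, max_species=4):
    """Random tiny survey for oracle-equivalence checks; at least one
    non-zero count guaranteed."""
    n_q = int(rng.integers(1, max_quadrats + 1))
    n_s = int(rng.integers(1, max_species + 1))
    species = [f"sp{i}" for i in range(n_s)]
    while True:
        quadrats = []
        for qid in range(1, n_q + 1):
            counts = {sp: int(rng.integers(0, 6)) for sp in species}
            quadrats.append(make_quadrat(counts, quadrat=qid))
        if any(n > 0 for q in quadrats for n in q.counts.values()):
            return quadrats
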