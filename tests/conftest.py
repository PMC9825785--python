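from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import toxpaths as tp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_kb_dir() -> Path:
    return DATA_DIR / "toy_kb"


@pytest.fixture(scope="session")
def toy_kb(toy_kb_dir) -> tp.KnowledgeBase:
    return tp.load_knowledge_base(toy_kb_dir, strict=True)


@pytest.fixture(scope="session")
def planted_world():
    """A strong-preset synthetic knowledge base with a planted
    compound -> pathway signal, shared across tests that only read it."""
    cfg = tp.SyntheticConfig(seed=11)
    kb = tp.generate_knowledge_base(cfg)
    observations, truth = tp.plant_compound_signal(kb, cfg, "PWY_001")
    return kb, cfg, observations, truth


def make_scores(score_map: dict[str, int], species_id: str = "sp") -> tp.GeneScoreVector:
    """GeneScoreVector over exactly the genes of ``score_map``."""
    universe = tuple(sorted(score_map))
    return tp.GeneScoreVector.from_counts(species_id, score_map, universe)


@pytest.fixture
def scores_factory():
    return make_scores


def random_score_vector(rng: np.random.Generator, n_genes: int) -> tp.GeneScoreVector:
    genes = tuple(f"g{i:03d}" for i in range(n_genes))
    scores = rng.integers(0, 4, size=n_genes)
    return tp.GeneScoreVector(species_id="sp", universe=genes, scores=scores)
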