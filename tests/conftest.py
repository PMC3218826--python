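import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from mirsolid.catalog import AnnotationCatalog, Feature, build_color_index
from mirsolid.mapping import MatchParams, assign_all
from mirsolid.quantify import count_features
from mirsolid.simulate import default_study_scenario, simulate_study


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def toy_catalog():
    """Hand-laid two-contig catalog with one feature per RNA class."""
    rng = np.random.default_rng(7)
    chr1 = _random_seq(rng, 600)
    chr2 = _random_seq(rng, 400)
    features = [
        Feature("pre-1", "miRNA_human", "chr1", 100, 160, "+"),
        Feature("mir-1-5p", "miRNA_human", "chr1", 100, 122, "+", "pre-1"),
        Feature("mir-1-3p", "miRNA_human", "chr1", 138, 160, "+", "pre-1"),
        Feature("trna-1", "tRNA", "chr1", 200, 272, "+"),
        Feature("pirna-1", "piRNA", "chr1", 300, 328, "-"),
        Feature("exon-1", "transcript", "chr2", 50, 250, "+"),
        Feature("sno-1", "snoRNA", "chr2", 300, 380, "+"),
    ]
    catalog = AnnotationCatalog(contigs={"chr1": chr1, "chr2": chr2}, features=features)
    build_color_index(catalog, 8)
    return catalog


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced-depth study simulation shared across test modules."""
    cfg = default_study_scenario(1)
    cfg.depth = 20_000
    catalog, truth, samples = simulate_study(cfg)
    return cfg, catalog, truth, samples


@pytest.fixture(scope="session")
def small_assignments(small_scenario):
    cfg, catalog, truth, samples = small_scenario
    table, summary = assign_all(samples, catalog, MatchParams(), adapter=cfg.adapter)
    return cfg, catalog, truth, table, summary


@pytest.fixture(scope="session")
def small_counts(small_assignments):
    cfg, catalog, truth, table, _ = small_assignments
    return truth, count_features(table, catalog, truth.conditions)
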