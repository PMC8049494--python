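import networkx as nx
import pandas as pd
import pytest

import twohit as th


@pytest.fixture
def triangle_net() -> nx.Graph:
    """A-B and B-C strong (w=2), A-C weak (w=0.5): the two-step route wins."""
    edges = pd.DataFrame(
        [("A", "B", 2.0), ("B", "C", 2.0), ("A", "C", 0.5)],
        columns=["gene_a", "gene_b", "weight"],
    )
    return th.build_network(edges, "absolute", 0.0)


@pytest.fixture
def path4_net() -> nx.Graph:
    """Path graph a-b-c-d with unit edge costs (weight 1)."""
    edges = pd.DataFrame(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)],
        columns=["gene_a", "gene_b", "weight"],
    )
    return th.build_network(edges, "absolute", 0.0)


@pytest.fixture
def toy_annotation() -> th.GeneAnnotation:
    """One chromosome, ten genes at unit spacing, CNV over positions 3-5."""
    return th.generate_annotation(
        n_chromosomes=1,
        genes_per_chromosome=10,
        cnv_regions=(("chr1", 3, 6, "cnv"),),
        rvis_distribution=("uniform", (0.0, 100.0)),
        seed=3,
    )


@pytest.fixture
def demo_screen() -> pd.DataFrame:
    """Seeded demo screen with three injected interactions (two +1, one -1)."""
    return th.generate_phenotype_screen(th.default_screen_config(0))
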