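import numpy as np
import pandas as pd
import pytest

from lncomp.synthetic_data import SimulationDesign, simulate_annotation, simulate_expression, simulate_probes
from lncomp.types import AnnotationSource, GeneModel, GenomeModel, ProbeAlignment

FIVE_TISSUES = (
    ("oocyte", 10, 2), ("two_cell", 6, 1), ("blastocyst", 12, 2),
    ("cumulus", 8, 1), ("granulosa", 10, 2),
)


@pytest.fixture
def small_genome():
    return GenomeModel(chromosomes=(("chr1", 1_000_000), ("chr2", 1_000_000)))


@pytest.fixture
def two_gene_source():
    """chr1: + gene with 2 exons; chr1: - gene downstream."""
    plus = GeneModel("GP", "chr1", "+", ((50, 200), (1_200, 1_400)))
    minus = GeneModel("GM", "chr1", "-", ((10_000, 10_500), (11_000, 11_600)))
    return AnnotationSource("src", (plus, minus))


@pytest.fixture
def default_design():
    return SimulationDesign(seed=11, module_sizes=(10, 10), tissue_specific_sets={"oocyte": 3})


@pytest.fixture
def simulated(default_design):
    bundle = simulate_annotation(default_design)
    probes, truth = simulate_probes(bundle, default_design)
    raw, meta, negctl, truth = simulate_expression(probes, default_design, truth)
    return {
        "design": default_design, "bundle": bundle, "probes": probes,
        "truth": truth, "raw": raw, "meta": meta, "negctl": negctl,
    }


def make_probe(probe_id, chrom, start, end, strand="+"):
    return ProbeAlignment(probe_id, chrom, start, end, strand)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
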