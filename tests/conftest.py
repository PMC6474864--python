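"""Shared fixtures: small seeded cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from xenosplit.pipeline import PipelineConfig, simulate_cohort
from xenosplit.quantify import build_gene_kmer_map
from xenosplit.synthetic_data import (
    CohortDesign,
    simulate_gene_pairs,
    simulate_reads,
)
from xenosplit.xenoclassify import build_index


@pytest.fixture(scope="session")
def toy_index():
    """The hand-enumerable two-sequence index (graft ACGTA, host TTTTT, k=3)."""
    return build_index(["ACGTA"], ["TTTTT"], k=3)


@pytest.fixture(scope="session")
def small_genes():
    return simulate_gene_pairs(60, stroma_proportion=0.3, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-gene, 4-pair cohort with reads, index and gene map (seeded)."""
    config = PipelineConfig(
        n_genes=120,
        design=CohortDesign(n_pairs=4, fragments_per_sample=6000, seed=11),
    )
    genes, design, truth, index, gmap = simulate_cohort(config)
    read_sets = {r.sample_id: r for r in simulate_reads(genes, design, truth)}
    return {
        "config": config,
        "genes": genes,
        "design": design,
        "truth": truth,
        "index": index,
        "gmap": gmap,
        "reads": read_sets,
    }


@pytest.fixture(scope="session")
def disjoint_gene_map():
    """Two random genes that share no canonical k-mer (verified)."""
    rng = np.random.default_rng(5)
    g1 = "".join(rng.choice(list("ACGT"), 300))
    g2 = "".join(rng.choice(list("ACGT"), 300))
    gmap = build_gene_kmer_map([("g1", g1), ("g2", g2)], k=11)
    assert not gmap.shared
    return gmap, g1, g2
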