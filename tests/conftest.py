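import pytest

from tastemine import annotate, search, simdata


@pytest.fixture(scope="session")
def spec7() -> simdata.SimSpec:
    return simdata.SimSpec(
        n_intact=20, n_partial=5, n_pseudo=5, divergence=0.1, seed=7
    )


@pytest.fixture(scope="session")
def genome7(spec7):
    genome, truth = simdata.simulate_genome(spec7)
    queries = simdata.simulate_queries(spec7)
    return genome, truth, queries


@pytest.fixture(scope="session")
def mined7(genome7):
    """Search + annotate run once on the seed-7 planted genome."""
    genome, truth, queries = genome7
    params = search.SearchParams()
    hits = search.search_genome(queries, genome, params)
    kept = search.filter_hits(hits, params)
    loci = [
        search.extend_locus(l, params, len(genome.contigs[l.contig_id]))
        for l in search.merge_hits(kept, params)
    ]
    models = annotate.annotate_loci(genome, loci, queries)
    return {"hits": hits, "loci": loci, "models": models}


@pytest.fixture()
def template_orf():
    """One clean template ORF with its protein (deterministic)."""
    import numpy as np

    rng = np.random.default_rng(0)
    prot = simdata.make_template_protein(rng)
    return simdata.make_orf(prot, rng), prot
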