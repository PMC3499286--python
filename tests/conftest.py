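import pytest

import capmap as cm


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed simulation shared by read-only tests."""
    cfg = cm.SimConfig(seed=11, n_genes=12, n_reads=400)
    genome, models, _ = cm.simulate_genome(cfg)
    reads, quals, truth = cm.simulate_reads(genome, models, cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genome_map": {r.id: r.sequence for r in genome},
        "models": models,
        "reads": reads,
        "quals": quals,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def noiseless_sim():
    """Error-free, fully 5'-complete reads: recovery oracles are exact."""
    cfg = cm.SimConfig(
        seed=23, n_genes=10, n_reads=300,
        seq_error_rate=0.0, polymorphism_rate=0.0, editing_rate=0.0,
        frac_duplicated=0.0, frac_pseudogene=0.0, full_length_prob=1.0,
    )
    genome, models, _ = cm.simulate_genome(cfg)
    reads, quals, truth = cm.simulate_reads(genome, models, cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genome_map": {r.id: r.sequence for r in genome},
        "models": models,
        "reads": reads,
        "quals": quals,
        "truth": truth,
    }
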