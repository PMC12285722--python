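import pytest

from retentia import SimConfig, make_maxent_fixture, simulate_gene, simulate_reads


@pytest.fixture(scope="session")
def default_gene():
    """Small synthetic gene with the default five-exon structure."""
    return simulate_gene(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_truth():
    """A modest simulated read set plus its gene (noise-free)."""
    cfg = SimConfig(n_reads=3000, seed=19)
    gene = simulate_gene(cfg)
    return gene, simulate_reads(gene)


@pytest.fixture(scope="session")
def uniform_maxent(tmp_path_factory):
    """Uniform-probability model tables in the reference file layout."""
    out = tmp_path_factory.mktemp("maxent")
    return make_maxent_fixture(str(out))


@pytest.fixture(scope="session")
def sim_files(tmp_path_factory):
    """On-disk GTF/FASTA/SAM/truth outputs of one simulation."""
    out = tmp_path_factory.mktemp("sim")
    prefix = str(out / "sim")
    cfg = SimConfig(n_reads=2000, seed=5)
    gene = simulate_gene(cfg, out_prefix=prefix)
    truth = simulate_reads(gene, out_prefix=prefix)
    return {"prefix": prefix, "gene": gene, "truth": truth, "config": cfg}
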