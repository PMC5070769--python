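import pytest

from mqtlnet import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_accessions=80, n_snps=800, n_genes=100, n_metabolites=8,
        n_conditions=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def high_signal_study():
    """Noise-light study where every method should recover the truth."""
    cfg = SimulationConfig(
        n_accessions=150, n_snps=1500, n_genes=120, n_metabolites=8,
        n_conditions=2, causal_variance_share=0.35, n_trans_per_metabolite=0,
        causal_edge_rate=1.0, planted_edge_fraction=0.0,
        external_tp_rate=1.0, external_fp_rate=0.0,
        timecourse_noise_sd=0.1, missing_fraction=0.0, seed=5,
    )
    return simulate_all(cfg)
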