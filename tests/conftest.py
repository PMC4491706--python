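import pytest
from hypothesis import HealthCheck, settings

import singpcr as s

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel():
    """20 homolog pairs used across module tests."""
    specs, pairs = s.make_homolog_pairs(20, frac_x_linked=0.3, seed=11)
    return specs, pairs


@pytest.fixture(scope="session")
def gdna_mixture_run():
    """A counts-level gDNA mixture simulation shared by quantification tests:
    350 pairs, five mixtures, log-normal bias constant across samples."""
    specs, pairs = s.make_homolog_pairs(350, frac_x_linked=0.05, seed=101)
    amps = [p.amplicon_id for p in pairs]
    bias = s.BiasModel.lognormal(amps, sd_log=0.5, mean_depth=5000, seed=102)
    designs = s.make_gdna_designs((0.1, 0.3, 0.5, 0.7, 0.9))
    counts, truth = s.simulate_gdna_counts(pairs, designs, bias, seed=103)
    return specs, pairs, bias, designs, counts, truth


@pytest.fixture(scope="session")
def emitted_sample(tmp_path_factory, small_panel):
    """Error-free FASTQ for two mixtures plus the two pure samples."""
    _, pairs = small_panel
    amps = [p.amplicon_id for p in pairs]
    bias = s.BiasModel.constant(amps, mean_depth=250, depth_sd_log=0.2)
    designs = s.make_gdna_designs((0.3, 0.7), include_pure=True)
    counts, truth = s.simulate_gdna_counts(pairs, designs, bias, seed=21)
    out = tmp_path_factory.mktemp("fastq")
    files = s.emit_fastq(counts, pairs, out, error_rate=0.0, seed=22)
    return pairs, counts, truth, files
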