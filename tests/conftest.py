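import pytest
from hypothesis import settings

from editkit import pipeline, synthio

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TINY = dict(genome_length=60_000, n_genes=15, n_editing_sites=120)


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """Small simulated study shared by read-level tests."""
    cfg = synthio.SimConfig(**TINY, seed=7)
    return synthio.simulate_study(cfg, tmp_path_factory.mktemp("tiny"))


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """The full default demo study plus pipeline results (run once)."""
    out = tmp_path_factory.mktemp("demo")
    study, manifest = pipeline.demo(seed=1, outdir=out)
    return study, manifest, out
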