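import pytest

from phytoscreen import RunConfig, SimConfig, run_screen, simulate_campaign, simulate_truth


@pytest.fixture(scope="session")
def small_config():
    """A 56-extract campaign (two cell plates) for fast end-to-end tests."""
    return SimConfig(n_extracts=56, seed=7)


@pytest.fixture(scope="session")
def small_campaign(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("campaign")
    truth, manifest = simulate_campaign(small_config, outdir)
    return truth, manifest, outdir


@pytest.fixture(scope="session")
def small_screen(small_campaign):
    truth, manifest, outdir = small_campaign
    config = RunConfig.from_manifest(manifest, outdir=str(outdir / "out"))
    return truth, run_screen(config)


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth of the default 375-extract library."""
    return simulate_truth(SimConfig(seed=11))

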