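import pytest

from rirkit.cli import PipelineConfig, run_pipeline, simulate_dataset


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """Toy simulated dataset (default preset, seed 17) with planted truth."""
    outdir = tmp_path_factory.mktemp("sim")
    truth = simulate_dataset(str(outdir), seed=17)
    return str(outdir), truth


@pytest.fixture(scope="session")
def toy_pipeline(toy_dataset, tmp_path_factory):
    """Full pipeline run on the toy dataset."""
    indir, truth = toy_dataset
    outdir = tmp_path_factory.mktemp("out")
    report = run_pipeline(PipelineConfig(indir=indir, outdir=str(outdir)))
    return report, str(outdir), truth
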