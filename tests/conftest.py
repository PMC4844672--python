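"""Shared fixtures: a toy PWM, a small synthetic study, and pipeline configs."""

import numpy as np
import pytest

from bindscape import PWM, SimConfig, gen_fixture
from bindscape.simulate import build_fixture

TRACK_NAMES = ("ref_rep1", "ref_rep2", "alt_rep1", "alt_rep2", "control")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pwm():
    """4-bp PWM with distinct integer weights; consensus ACGT, min score -28."""
    raw = np.array(
        [
            [0.0, -2.0, -5.0, -7.0],
            [-3.0, 0.0, -6.0, -4.0],
            [-8.0, -1.0, 0.0, -2.0],
            [-5.0, -3.0, -7.0, 0.0],
        ]
    )
    return PWM(raw)


def pipeline_config(fixture_dir, seed=0, **extra):
    """Config dict pointing at a generated fixture directory."""
    conf = {
        "genome": str(fixture_dir / "genome.fa"),
        "pwm": str(fixture_dir / "pwm.tsv"),
        "regions": str(fixture_dir / "regions.bed"),
        "chrom_sizes": str(fixture_dir / "chrom_sizes.tsv"),
        "dhs_open": str(fixture_dir / "dhs_open.bed"),
        "dhs_signal": str(fixture_dir / "dhs_signal.bedgraph"),
        "seed": seed,
    }
    for name in TRACK_NAMES:
        conf[name] = str(fixture_dir / f"{name}.bedgraph")
    conf.update(extra)
    return conf


SMALL_SIM = dict(
    seed=11,
    genome_length=400_000,
    n_regions=60,
    n_background_peaks=30,
    n_zero_alt=2,
)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A small landscape-mode study written to disk (60 regions, 0.4 Mb)."""
    outdir = tmp_path_factory.mktemp("fixture") / "small"
    manifest = gen_fixture(SimConfig(**SMALL_SIM), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def small_fixture_objects():
    """The same small study, in memory."""
    return build_fixture(SimConfig(**SMALL_SIM))
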