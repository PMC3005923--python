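import pytest

from surfqc import builtin_layout, generate_flowcell, read_fastq
from surfqc.metrics import accumulate_tile
from surfqc.synthetic import Effects, GradientEffect


@pytest.fixture(scope="session")
def mini_layout():
    return builtin_layout("mini_20")


@pytest.fixture(scope="session")
def flat_flowcell(mini_layout, tmp_path_factory):
    """5000 bias-free basespace reads on the 5x4 miniature flowcell."""
    out = tmp_path_factory.mktemp("flat_fc")
    return generate_flowcell(mini_layout, 5000, 20, out, seed=11)


@pytest.fixture(scope="session")
def flat_tiles(flat_flowcell, mini_layout):
    reader = read_fastq(flat_flowcell.paths["fastq"], mini_layout)
    tiles = accumulate_tile(iter(reader), mini_layout, (5, 5))
    return tiles, reader


@pytest.fixture(scope="session")
def gradient_flowcell(mini_layout, tmp_path_factory):
    """20k reads with a 0.05 within-tile A-gradient."""
    out = tmp_path_factory.mktemp("grad_fc")
    eff = Effects(gradient=GradientEffect("A", 0.05))
    return generate_flowcell(mini_layout, 20_000, 25, out, effects=eff, seed=5)
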