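import numpy as np
import pytest

from mitoscreen.simulate import MssSpec, OrfSpec, RepeatSpec, gen_panel


@pytest.fixture(scope="session")
def small_panel():
    """60 kb circular panel with one planted MSS carrying a TM-positive ORF."""
    return gen_panel(
        21, backbone_len=60_000, n_genomes=4,
        mss_spec=[MssSpec(1000, ())],
        orf_spec=[OrfSpec(n_codons=90, hydrophobic=True, in_mss=0)],
    )


@pytest.fixture(scope="session")
def rich_panel():
    """100 kb panel with several MSSs, a duplicated MSS and a planted repeat."""
    return gen_panel(
        11, backbone_len=100_000, n_genomes=6,
        mss_spec=[
            MssSpec(500, ()),
            MssSpec(800, (0, 1, 2)),
            MssSpec(300, (3,)),
            MssSpec(1200, (0,), duplicate=True),
            MssSpec(220, (1, 2, 3, 4)),
        ],
        orf_spec=[OrfSpec(n_codons=90, hydrophobic=True, in_mss=1)],
        repeat_spec=[RepeatSpec(length=2000)],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
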