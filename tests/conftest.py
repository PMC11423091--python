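import numpy as np
import pytest
from hypothesis import settings

# property tests must behave identically on every run
settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240815)


@pytest.fixture
def tiny_tped(tmp_path):
    """Three samples, three variants, written by hand.

    snp1 calls: A A | A G | G G  -> allele counts A:3, G:3 (tie at 0.5)
    snp2 calls: C C | C C | C T  -> T minor (1/6)
    snp3 calls: 0 0 | T T | T A  -> one missing call, A minor (1/4)
    """
    tped = tmp_path / "toy.tped"
    tfam = tmp_path / "toy.tfam"
    tped.write_text(
        "1 snp1 0 100 A A A G G G\n"
        "1 snp2 0 200 C C C C C T\n"
        "2 snp3 0 300 0 0 T T T A\n")
    tfam.write_text(
        "F1 I1 0 0 1 -9\nF2 I2 0 0 1 -9\nF3 I3 0 0 2 -9\n")
    return tped, tfam
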