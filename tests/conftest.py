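import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_gff3(tmp_path):
    """A 3-gene single-replicon genome on disk (GFF3 + protein FASTA)."""
    gff = tmp_path / "G1.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t100\t400\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tgene\t500\t900\t.\t-\t.\tID=g2\n"
        "chr1\tsrc\tgene\t1000\t1300\t.\t+\t.\tID=g3\n"
    )
    faa = tmp_path / "G1.faa"
    faa.write_text(">g1\nMKV*\n>g2\nMTTG\n>g3\nMAA\n")
    return gff, faa
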