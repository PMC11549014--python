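import numpy as np
import pysam
import pytest

from haplocall.simulator import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_sample(tmp_path_factory):
    """A small written diploid sample with SNVs and indels, no read errors."""
    cfg = SimConfig(ref_length=12_000, snv_rate=2e-3, ins_rate=3e-4,
                    del_rate=3e-4, het_fraction=0.5, base_error_rate=0.0,
                    mean_depth=40, seed=42)
    sample = simulate(cfg)
    sample.write(str(tmp_path_factory.mktemp("sim_sample")))
    return sample


@pytest.fixture(scope="session")
def sim_bam(sim_sample):
    with pysam.AlignmentFile(sim_sample.paths.bam) as bam:
        yield bam


@pytest.fixture(scope="session")
def sim_fasta(sim_sample):
    with pysam.FastaFile(sim_sample.paths.fasta) as fasta:
        yield fasta


class StringReference:
    """pysam.FastaFile-compatible fetch over in-memory sequences."""

    def __init__(self, **seqs):
        self.seqs = seqs
        self.references = list(seqs)
        self.lengths = [len(s) for s in seqs.values()]

    def fetch(self, chrom, start, end):
        return self.seqs[chrom][max(0, start):end]


@pytest.fixture
def string_reference():
    return StringReference
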