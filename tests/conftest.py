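import numpy as np
import pytest

from ipscvar import normalization as nz
from ipscvar import synthetic_data as sd


@pytest.fixture(scope="session")
def default_design():
    return sd.default_study_design()


@pytest.fixture(scope="session")
def small_study():
    """One simulated study at the default (panel-regime) truth, 800 genes."""
    cfg = sd.SimulationConfig(n_genes=800, seed=12345)
    return sd.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_log2fpkm(small_study):
    fpkm = nz.compute_fpkm(small_study["counts"])
    return nz.log_transform(fpkm)


def make_sam(path, records):
    """Write a minimal name-sorted SAM file from (name, flag, chrom, pos,
    mapq, cigar, rnext, pnext, tlen, nm) tuples."""
    header = (
        "@HD\tVN:1.6\tSO:queryname\n"
        "@SQ\tSN:chr1\tLN:250000000\n"
        "@SQ\tSN:chr2\tLN:250000000\n"
    )
    lines = [header]
    for name, flag, chrom, pos, mapq, cigar, rnext, pnext, tlen, nm in records:
        lines.append(
            f"{name}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t{rnext}\t{pnext}\t"
            f"{tlen}\t{'A' * 10}\t{'I' * 10}\tNM:i:{nm}\n"
        )
    path.write_text("".join(lines))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
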