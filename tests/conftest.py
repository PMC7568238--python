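import numpy as np
import pytest

from regdomain.genome import GeneRecord, GenomicInterval


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


def gene(gene_id, chrom, start, end, strand="+"):
    return GeneRecord(gene_id, GenomicInterval(chrom, start, end, name=gene_id, strand=strand))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_genes(rng, n, chroms=("chr1", "chr2"), max_pos=100_000):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, max_pos))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "+":
            out.append(gene(f"g{i:04d}", chrom, pos, pos + 100, "+"))
        else:
            out.append(gene(f"g{i:04d}", chrom, max(0, pos - 99), pos + 1, "-"))
    return out
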