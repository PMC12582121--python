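import numpy as np
import pandas as pd
import pytest

from ncrbp.config import SimConfig


@pytest.fixture
def small_cfg() -> SimConfig:
    """A desk-sized configuration exercising every generator quickly."""
    return SimConfig(
        seed=11,
        n_genes=100,
        screen_depth=100_000,
        n_transcripts=60,
        n_sites_per_sample=150,
    )


@pytest.fixture
def toy_annotation() -> pd.DataFrame:
    """Two transcripts, one per strand, with fixed feature intervals."""
    return pd.DataFrame(
        [
            # plus-strand coding gene: 5'UTR [100,200) CDS [200,800) 3'UTR [800,1000)
            ("chr1", 100, 200, "+", "five_prime_utr", "GA", "TA", "protein_coding"),
            ("chr1", 200, 800, "+", "CDS", "GA", "TA", "protein_coding"),
            ("chr1", 800, 1000, "+", "three_prime_utr", "GA", "TA", "protein_coding"),
            # minus-strand coding gene: genomic left-to-right is 3'UTR, CDS, 5'UTR
            ("chr1", 2000, 2200, "-", "three_prime_utr", "GB", "TB", "protein_coding"),
            ("chr1", 2200, 2900, "-", "CDS", "GB", "TB", "protein_coding"),
            ("chr1", 2900, 3000, "-", "five_prime_utr", "GB", "TB", "protein_coding"),
            # lncRNA on plus strand
            ("chr1", 4000, 4500, "+", "noncoding_exon", "GC", "TC", "lncRNA"),
        ],
        columns=["chrom", "start", "end", "strand", "feature", "gene_id",
                 "transcript_id", "biotype"],
    )


def make_sites(rows) -> pd.DataFrame:
    """rows: (chrom, pos, strand[, condition])"""
    recs = []
    for r in rows:
        chrom, pos, strand = r[:3]
        cond = r[3] if len(r) > 3 else "norm"
        recs.append(
            {"chrom": chrom, "pos": pos, "strand": strand, "condition": cond,
             "replicate": 1, "score": 1.0}
        )
    return pd.DataFrame(recs)


def make_peaks(rows) -> pd.DataFrame:
    """rows: (chrom, start, end, strand[, condition])"""
    recs = []
    for r in rows:
        chrom, start, end, strand = r[:4]
        cond = r[4] if len(r) > 4 else "norm"
        recs.append(
            {"chrom": chrom, "start": start, "end": end, "strand": strand,
             "condition": cond, "n_sites": 1, "score": 1.0}
        )
    return pd.DataFrame(recs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
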