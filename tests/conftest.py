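import numpy as np
import pandas as pd
import pytest

from flankpref import hairpin, simulate


@pytest.fixture(scope="session")
def layout():
    return simulate.SubstrateLayout()


@pytest.fixture(scope="session")
def pref_table():
    """Deterministic C(-2)/C(-1)-preferring rate table, geometric mean 1."""
    return simulate.dnmt3c_like_rate_table()


@pytest.fixture(scope="session")
def clean_batch(layout, pref_table):
    """2000 noise-free reads plus truth and the processed call table."""
    kin = simulate.TrueKinetics(pref_table, {0: 1.0})
    reads, truth = simulate.simulate_reaction_reads(
        layout, kin, 0, 2000, simulate.NoiseModel(seed=11))
    calls, log = hairpin.process_reads(reads, layout, dedup=False)
    return reads, truth, calls, log


def make_read(seq, q=40, rid="r0"):
    return hairpin.ReadRecord(rid, seq, [q] * len(seq))


@pytest.fixture(scope="session")
def toy_genome_sites():
    """100-bp toy genome with 3 CpGs and hand-set coverages {5, 5, 2}."""
    g = ("A" * 20) + "ACGT" + ("A" * 16) + "TCGA" + ("A" * 16) + "GCGT" + ("A" * 40)
    pos = [i for i in range(len(g) - 1) if g[i: i + 2] == "CG"]
    calls = pd.DataFrame({
        "chrom": "t", "pos": pos, "strand": "+",
        "methylated_count": [2, 3, 1], "total_count": [5, 5, 2],
    })
    return g, calls, pos
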