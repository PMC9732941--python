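import numpy as np
import pandas as pd
import pytest

from te_reguscan.sim import (
    DESpec,
    ExpressionSpec,
    PeakSpec,
    ReporterSpec,
    SimConfig,
    TEFamilySpec,
)


@pytest.fixture
def toy_config():
    """1 chromosome of 100 kb, two TE families, small everything."""
    return SimConfig(
        genome_chrom_sizes={"chr1": 100_000},
        te_family_specs=[
            TEFamilySpec("TOYDNA1", "DNA", "Eutheria", 20, 200, 0.0),
            TEFamilySpec("TOYLTR1", "LTR", "Primates", 20, 200, 0.5),
        ],
        peak_spec=PeakSpec(n_peaks=100, mean_length=150),
        expression_spec=ExpressionSpec(n_genes=50),
        de_spec=DESpec(n_genes_per_set=50),
        reporter_spec=ReporterSpec(n_constructs=20, n_replicates=5),
        seed=7,
    )


def random_te_frame(rng, n=50, chrom_len=10_000, n_copies=10, frag=True):
    """Random fragmented TE annotation for interval-engine tests."""
    rows = []
    for i in range(n):
        cid = f"c{rng.integers(0, n_copies)}"
        fam = f"F{rng.integers(0, 3)}"
        start = int(rng.integers(0, chrom_len - 200))
        length = int(rng.integers(20, 200))
        rows.append(("chr1", start, start + length, fam, "DNA", "Eutheria", cid, 0, "."))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "family", "te_class", "age_class",
                 "copy_id", "fragment_index", "strand"],
    )


def random_peak_frame(rng, n=30, chrom_len=10_000):
    starts = rng.integers(0, chrom_len - 300, size=n)
    lengths = rng.integers(50, 300, size=n)
    return pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + lengths,
         "name": [f"p{i}" for i in range(n)]}
    )


def random_rooted_tree(rng, n_tips, multifurcating=False):
    """Random rooted tree as a Newick string with labelled tips t0..t{n-1}."""
    nodes = [f"t{i}:1" for i in range(n_tips)]
    while len(nodes) > 1:
        k = 2
        if multifurcating and len(nodes) > 2 and rng.random() < 0.3:
            k = 3
        pick = rng.choice(len(nodes), size=min(k, len(nodes)), replace=False)
        merged = "(" + ",".join(nodes[i] for i in sorted(pick)) + "):1"
        nodes = [n for i, n in enumerate(nodes) if i not in pick] + [merged]
    return nodes[0] + ";"
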