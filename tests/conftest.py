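import numpy as np
import pandas as pd
import pytest

from mycophylo import phylo
from mycophylo.tables import PairedOtuTable


def make_table(data: dict, samples: list[str]) -> PairedOtuTable:
    """Build a paired table from {otu: {(sample, fraction): count}}."""
    cols = pd.MultiIndex.from_product([samples, ["DNA", "RNA"]],
                                      names=["sample", "fraction"])
    frame = pd.DataFrame(0, index=pd.Index(sorted(data), name="otu_id"),
                         columns=cols, dtype=np.int64)
    for otu, cells in data.items():
        for key, count in cells.items():
            frame.loc[otu, key] = count
    return PairedOtuTable(frame)


@pytest.fixture
def balanced_four_tip_tree():
    """((A:1,B:1):1,(C:1,D:1):1) — the standard PIC hand example."""
    return phylo.read_newick("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);")


@pytest.fixture
def star_tree():
    newick = "(" + ",".join(f"t{i}:1.0" for i in range(8)) + ");"
    return phylo.read_newick(newick)


@pytest.fixture
def toy_table():
    """3 samples; x present in every column, y missing from one RNA column."""
    return make_table(
        {
            "x": {(s, f): 5 for s in ["s1", "s2", "s3"] for f in ["DNA", "RNA"]},
            "y": {
                ("s1", "DNA"): 2, ("s1", "RNA"): 2,
                ("s2", "DNA"): 2, ("s2", "RNA"): 0,
                ("s3", "DNA"): 2, ("s3", "RNA"): 2,
            },
        },
        ["s1", "s2", "s3"],
    )
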