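import io as _io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from reactocap.io_formats import (
    RANKS,
    AsvTable,
    PhyloTree,
    SampleMetadata,
    TaxonomyTable,
)

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1):0;"


def tree_from_newick(newick: str) -> PhyloTree:
    return PhyloTree(TreeNode.read(_io.StringIO(newick), format="newick"))


@pytest.fixture
def toy_tree() -> PhyloTree:
    return tree_from_newick(TOY_NEWICK)


@pytest.fixture
def toy_table() -> AsvTable:
    counts = np.array(
        [
            [10, 10, 10, 10],
            [10, 0, 0, 0],
            [0, 5, 5, 0],
        ]
    )
    return AsvTable(("s1", "s2", "s3"), ("A", "B", "C", "D"), counts)


def make_taxonomy(rows: dict[str, list[str]]) -> TaxonomyTable:
    """rows: asv id -> 7 rank names ('' = unassigned)."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyTable(df)


def make_metadata(samples: dict[str, str], sample_type: str = "digesta") -> SampleMetadata:
    """samples: sample id -> diet group."""
    df = pd.DataFrame(
        {
            "diet": pd.Series(samples),
            "sample_type": sample_type,
            "tank": "T1",
            "run": "run1",
        }
    )
    return SampleMetadata(df)


def random_bifurcating_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random rooted bifurcating newick, written independently of the package."""
    nodes = [f"T{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(merged)
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"
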