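import numpy as np
import pandas as pd
import pytest

from clonecn.core import CloneProportions, FractionalCN, SegmentTable
from clonecn.tree import CloneTree


@pytest.fixture
def chain_tree() -> CloneTree:
    """diploid -> clone1 -> clone2 -> clone3 (linear)."""
    return CloneTree(
        [("diploid", "clone1"), ("clone1", "clone2"), ("clone2", "clone3")]
    )


@pytest.fixture
def branched_tree() -> CloneTree:
    """clone1 with two children, one of which has a further child."""
    return CloneTree(
        [
            ("diploid", "clone1"),
            ("clone1", "clone2"),
            ("clone1", "clone3"),
            ("clone3", "clone4"),
        ]
    )


@pytest.fixture
def two_segments() -> SegmentTable:
    return SegmentTable(
        pd.DataFrame(
            {
                "segment": ["s1", "s2"],
                "chrom": ["1", "2"],
                "start": [1, 1],
                "end": [1_000_000, 3_000_000],
                "arm": ["p", "p"],
            }
        )
    )


@pytest.fixture
def chain_proportions(chain_tree) -> CloneProportions:
    u = np.array(
        [
            [0.2, 0.4],   # diploid (normal)
            [0.5, 0.1],   # clone1
            [0.2, 0.2],   # clone2
            [0.1, 0.3],   # clone3
        ]
    )
    return CloneProportions(
        ("diploid", "clone1", "clone2", "clone3"), ("R1", "R2"), u
    )


def make_fractional(segments, samples, est, half_width=0.2) -> FractionalCN:
    """FractionalCN with symmetric bounds around the given estimates."""
    est = np.asarray(est, dtype=float)
    lo = np.maximum(est - half_width, 0.0)
    hi = est + half_width
    return FractionalCN(tuple(segments), tuple(samples), est, lo, hi)
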