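"""Readers and writers for the tab-separated interchange formats.

Formats
-------
tree.tsv            two columns ``parent<TAB>child`` (header required), or a
                    Newick file with named internal nodes (extension ``.nwk``/
                    ``.newick`` or content starting with ``(``).
proportions.tsv     ``clone  sample  proportion`` (long format).
fractional_cn.tsv   ``segment chrom start end sample fA fA_lo fA_hi fB fB_lo fB_hi``.
clone_cn.tsv        ``segment chrom start end clone cnA cnB`` (output).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CloneCNProfile,
    CloneProportions,
    FractionalCN,
    SegmentTable,
    ValidationError,
    chrom_sort_key,
)
from .tree import CloneTree

__all__ = [
    "read_tree",
    "read_proportions",
    "read_fractional",
    "read_inputs",
    "write_clone_profile",
    "read_clone_profile",
]


def read_tree(path: str | Path) -> CloneTree:
    path = Path(path)
    text = path.read_text().strip()
    if path.suffix in {".nwk", ".newick"} or text.startswith("("):
        return CloneTree.from_newick(text)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"parent", "child"} <= set(df.columns):
        raise ValidationError(f"{path}: tree file needs 'parent' and 'child' columns")
    return CloneTree(list(df[["parent", "child"]].itertuples(index=False, name=None)))


def read_proportions(path: str | Path) -> CloneProportions:
    df = pd.read_csv(path, sep="\t")
    if not {"clone", "sample", "proportion"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns clone, sample, proportion")
    return CloneProportions.from_frame(df)


def read_fractional(path: str | Path) -> tuple[SegmentTable, FractionalCN]:
    df = pd.read_csv(path, sep="\t")
    fractional = FractionalCN.from_frame(df)
    seg_df = (
        df[["segment", "chrom", "start", "end"]]
        .drop_duplicates(subset="segment")
        .reset_index(drop=True)
    )
    segments = SegmentTable(seg_df)
    # keep the fractional table aligned with genomic sort order
    order = [s for s in segments.segments]
    idx = [fractional.segments.index(s) for s in order]
    fractional = FractionalCN(
        tuple(order),
        fractional.samples,
        fractional.est[idx],
        fractional.lo[idx],
        fractional.hi[idx],
    )
    return segments, fractional


def read_inputs(
    tree_path: str | Path,
    proportions_path: str | Path,
    fractional_path: str | Path,
) -> tuple[CloneTree, CloneProportions, SegmentTable, FractionalCN]:
    """Read and cross-validate the three inputs of the inference problem."""
    tree = read_tree(tree_path)
    proportions = read_proportions(proportions_path)
    segments, fractional = read_fractional(fractional_path)

    tree_clones = set(tree.nodes)
    prop_clones = set(proportions.clones)
    if tree_clones - prop_clones:
        raise ValidationError(
            f"clones in tree but not in proportions: {sorted(tree_clones - prop_clones)}"
        )
    if prop_clones - tree_clones:
        raise ValidationError(
            f"clones in proportions but not in tree: {sorted(prop_clones - tree_clones)}"
        )
    return tree, proportions, segments, fractional


def write_clone_profile(
    profile: CloneCNProfile,
    segments: SegmentTable,
    path: str | Path,
) -> None:
    """Write a clone profile as long-format TSV in deterministic order."""
    missing = set(segments.segments) - set(profile.segments)
    if missing:
        raise ValidationError(f"profile is missing segments: {sorted(missing)}")
    df = profile.to_frame(segments)
    df["_key"] = [
        (chrom_sort_key(c), s, cl)
        for c, s, cl in zip(df["chrom"], df["start"], df["clone"])
    ]
    df = df.sort_values("_key", kind="mergesort").drop(columns="_key")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_clone_profile(path: str | Path) -> tuple[SegmentTable, CloneCNProfile]:
    df = pd.read_csv(path, sep="\t")
    required = {"segment", "chrom", "start", "end", "clone", "cnA", "cnB"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    seg_df = df[["segment", "chrom", "start", "end"]].drop_duplicates("segment")
    segments = SegmentTable(seg_df.reset_index(drop=True))
    segs = segments.segments
    clones = list(dict.fromkeys(df["clone"].astype(str)))
    m, n = len(segs), len(clones)
    cA = np.full((m, n), -1, dtype=np.int64)
    cB = np.full((m, n), -1, dtype=np.int64)
    si = {s: i for i, s in enumerate(segs)}
    ci = {c: j for j, c in enumerate(clones)}
    for row in df.itertuples(index=False):
        cA[si[str(row.segment)], ci[str(row.clone)]] = row.cnA
        cB[si[str(row.segment)], ci[str(row.clone)]] = row.cnB
    if (cA < 0).any():
        i, j = np.unravel_index(int(np.argmax(cA < 0)), cA.shape)
        raise ValidationError(f"missing copy number for segment {segs[i]!r}, clone {clones[j]!r}")
    return segments, CloneCNProfile(tuple(segs), tuple(clones), cA, cB)
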