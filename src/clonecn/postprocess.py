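"""Clone-level analytics on inferred copy-number profiles.

Ploidy, whole-genome doubling calls, per-edge event calling at segment and
chromosome-arm level, interval-event counting, clone classification by
anatomical site, and the clone copy number diversity (CCD) score.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .core import CloneCNProfile, CloneProportions, FractionalCN, SegmentTable, ValidationError
from .tree import CloneTree, NORMAL_CLONE

__all__ = [
    "clone_ploidy",
    "detect_wgd",
    "call_segment_events",
    "call_arm_events",
    "sample_level_arm_loh",
    "count_scnas_per_edge",
    "classify_clones",
    "compute_ccd",
]

logger = logging.getLogger(__name__)

WGD_RATIO = 1.5
ARM_EVENT_FRACTION = 0.9
ARM_LOH_PARENT_MAX = 0.2
SAMPLE_ARM_LOH_FRACTION = 0.98
SAMPLE_ARM_LOH_CN = 0.5


def _states(profile: CloneCNProfile, clone: str, tree: CloneTree) -> np.ndarray:
    if clone == tree.root:
        return np.ones((len(profile.segments), 2), dtype=np.int64)
    return profile.column(clone)


def clone_ploidy(profile: CloneCNProfile, segments: SegmentTable) -> pd.Series:
    """Length-weighted mean total copy number per clone."""
    order = [profile.segments.index(s) for s in segments.segments]
    w = segments.lengths
    total = (profile.cA + profile.cB)[order]
    p = (total * w[:, None]).sum(axis=0) / w.sum()
    return pd.Series(p, index=list(profile.clones), name="ploidy")


def detect_wgd(
    profile: CloneCNProfile, tree: CloneTree, segments: SegmentTable
) -> pd.Series:
    """Flag genome-doubled clones by parent (or grandparent) total-CN ratio.

    A clone is genome-doubled when the length-weighted mean ratio of its
    total copy number to its parent's exceeds 1.5; failing that, when the
    ratio to its grandparent exceeds 1.5 and the parent itself is not
    already flagged.  Segments where the ancestor total is 0 are excluded.
    """
    order = [profile.segments.index(s) for s in segments.segments]
    w = segments.lengths

    def ratio(child: str, ancestor: str) -> float:
        cc = _states(profile, child, tree).sum(axis=1)[order]
        ca = _states(profile, ancestor, tree).sum(axis=1)[order]
        keep = ca > 0
        if not keep.any():
            return 0.0
        return float(((cc[keep] / ca[keep]) * w[keep]).sum() / w[keep].sum())

    flags: dict[str, bool] = {}
    for clone in tree.tumour_clones:  # preorder: parents first
        parent = tree.parent(clone)
        flagged = ratio(clone, parent) > WGD_RATIO
        if not flagged:
            grandparent = tree.parent(parent)
            if grandparent is not None and not flags.get(parent, False):
                flagged = ratio(clone, grandparent) > WGD_RATIO
        flags[clone] = flagged
    return pd.Series(flags, name="wgd")


def call_segment_events(
    profile: CloneCNProfile, tree: CloneTree, ploidy: pd.Series
) -> pd.DataFrame:
    """Per-edge, per-segment event flags.

    gain: either allele increases; loss: either decreases; LOH: an allele
    drops from > 0 to 0; amplification: for either allele the child exceeds
    twice the parent, is at least 4, and exceeds the child's ploidy.
    """
    rows = []
    for parent, child in tree.edges:
        cp = _states(profile, parent, tree)
        cc = _states(profile, child, tree)
        delta = cc - cp
        p_child = float(ploidy[child])
        amp = ((cc > 2 * cp) & (cc >= 4) & (cc > p_child)).any(axis=1)
        for i, seg in enumerate(profile.segments):
            rows.append(
                {
                    "parent": parent,
                    "child": child,
                    "segment": seg,
                    "deltaA": int(delta[i, 0]),
                    "deltaB": int(delta[i, 1]),
                    "gain": bool((delta[i] > 0).any()),
                    "loss": bool((delta[i] < 0).any()),
                    "loh": bool(((cp[i] > 0) & (cc[i] == 0)).any()),
                    "amplification": bool(amp[i]),
                }
            )
    return pd.DataFrame(rows)


def call_arm_events(
    edge_events: pd.DataFrame,
    segments: SegmentTable,
    profile: CloneCNProfile,
    tree: CloneTree,
) -> pd.DataFrame:
    """Arm-level event calls per edge from segment-level flags.

    An arm carries a gain/loss/amplification when >= 90% of its analysed
    length is affected for either allele; arm LOH additionally requires
    <= 20% of the arm at copy 0 in the parent (per allele).
    """
    if "arm" not in segments.frame.columns:
        raise ValidationError("segment table has no 'arm' column")
    seg_frame = segments.frame.set_index("segment")
    lengths = seg_frame["end"] - seg_frame["start"] + 1
    rows = []
    for (parent, child), grp in edge_events.groupby(["parent", "child"], sort=False):
        cp = _states(profile, parent, tree)
        cc = _states(profile, child, tree)
        seg_idx = {s: i for i, s in enumerate(profile.segments)}
        grp = grp.set_index("segment")
        for (chrom, arm), arm_segs in seg_frame.groupby(["chrom", "arm"], sort=False):
            segs = [s for s in arm_segs.index if s in grp.index]
            if not segs:
                continue
            w = lengths.loc[segs].to_numpy(dtype=float)
            total = w.sum()
            if total <= 0:
                warnings.warn(f"arm {chrom}{arm} has zero analysed length; skipped")
                continue
            idx = [seg_idx[s] for s in segs]
            sub = grp.loc[segs]
            out = {"parent": parent, "child": child, "chrom": chrom, "arm": arm}
            for flag in ("gain", "loss", "amplification"):
                frac = (w * sub[flag].to_numpy(dtype=float)).sum() / total
                out[flag] = bool(frac >= ARM_EVENT_FRACTION)
            loh = False
            for a in range(2):
                child_zero = (cc[idx, a] == 0).astype(float)
                parent_zero = (cp[idx, a] == 0).astype(float)
                if (w * child_zero).sum() / total >= ARM_EVENT_FRACTION and (
                    w * parent_zero
                ).sum() / total <= ARM_LOH_PARENT_MAX:
                    loh = True
            out["loh"] = loh
            rows.append(out)
    return pd.DataFrame(rows)


def sample_level_arm_loh(
    fractional: FractionalCN, segments: SegmentTable
) -> pd.DataFrame:
    """Arm LOH calls visible from bulk samples alone.

    An arm is called in a sample when at least 98% of its analysed length has
    a fractional copy number below 0.5 for a single allele.
    """
    if "arm" not in segments.frame.columns:
        raise ValidationError("segment table has no 'arm' column")
    seg_frame = segments.frame
    seg_idx = {s: i for i, s in enumerate(fractional.segments)}
    rows = []
    for (chrom, arm), arm_segs in seg_frame.groupby(["chrom", "arm"], sort=False):
        w = (arm_segs["end"] - arm_segs["start"] + 1).to_numpy(dtype=float)
        idx = [seg_idx[s] for s in arm_segs["segment"]]
        total = w.sum()
        for r, sample in enumerate(fractional.samples):
            called = False
            for a in range(2):
                low = (fractional.est[idx, r, a] < SAMPLE_ARM_LOH_CN).astype(float)
                if (w * low).sum() / total >= SAMPLE_ARM_LOH_FRACTION:
                    called = True
            rows.append(
                {"chrom": chrom, "arm": arm, "sample": sample, "arm_loh": called}
            )
    return pd.DataFrame(rows)


def count_scnas_per_edge(
    profile: CloneCNProfile, tree: CloneTree, segments: SegmentTable
) -> pd.DataFrame:
    """Interval-event counts per edge.

    Per allele and chromosome, a maximal run of consecutive segments (in
    genomic order) sharing the same non-zero copy-number delta counts as one
    gain or one loss; the per-edge total is the sum over chromosomes and
    alleles.  Runs of different amplitude do not merge.
    """
    order = [profile.segments.index(s) for s in segments.segments]
    chroms = segments.chroms
    rows = []
    for parent, child in tree.edges:
        delta = (_states(profile, child, tree) - _states(profile, parent, tree))[order]
        n_gain = n_loss = 0
        for a in range(2):
            prev_chrom = None
            prev_delta = 0
            for i in range(len(order)):
                d = int(delta[i, a])
                new_run = d != 0 and (chroms[i] != prev_chrom or d != prev_delta)
                if new_run:
                    if d > 0:
                        n_gain += 1
                    else:
                        n_loss += 1
                prev_chrom = chroms[i]
                prev_delta = d
        rows.append(
            {
                "parent": parent,
                "child": child,
                "n_gains": n_gain,
                "n_losses": n_loss,
                "n_scnas": n_gain + n_loss,
            }
        )
    return pd.DataFrame(rows)


def classify_clones(
    tree: CloneTree,
    proportions: CloneProportions,
    sites: dict[str, str],
    presence_threshold: float = 0.0,
) -> pd.Series:
    """Label tumour clones by anatomical spread.

    ``sites`` maps each sample to ``primary``, ``metastasis`` or
    ``lymph_node`` (lymph nodes count as metastatic sites here).  Presence is
    clone-or-descendant proportion above the threshold, matching the
    mutation-sharing semantics of SNV-based clone calling.  Returns a frame
    indexed by clone with a ``clone_class`` label (``MRCA``, ``shared``,
    ``seeding``, ``primary-specific`` or ``metastasis-specific``) and an
    ``is_seeding`` flag; the flag can mark the MRCA itself when the
    metastasis was seeded truncally (the MRCA is then the most recent shared
    clone, while keeping its MRCA class label).
    """
    unknown = set(sites.values()) - {"primary", "metastasis", "lymph_node"}
    if unknown:
        raise ValidationError(f"unknown site labels: {sorted(unknown)}")
    clones = tree.tumour_clones
    u = proportions.for_clones(clones)
    primary_samples = [i for i, s in enumerate(proportions.samples) if sites.get(s) == "primary"]
    met_samples = [
        i
        for i, s in enumerate(proportions.samples)
        if sites.get(s) in ("metastasis", "lymph_node")
    ]

    idx = {c: j for j, c in enumerate(clones)}

    def present_in(clone: str, sample_ids: list[int]) -> bool:
        group = [idx[clone]] + [idx[d] for d in tree.descendants(clone)]
        return bool((u[np.ix_(group, sample_ids)] > presence_threshold).any())

    shared = {
        c for c in clones if present_in(c, primary_samples) and present_in(c, met_samples)
    }
    seeding = {
        c for c in shared if not any(d in shared for d in tree.descendants(c))
    }  # most recent shared clones; may be the MRCA itself (truncal seeding)
    rows = {}
    for clone in clones:
        if clone == tree.mrca:
            label = "MRCA"
        elif clone in seeding:
            label = "seeding"
        elif clone in shared:
            label = "shared"
        elif present_in(clone, met_samples):
            label = "metastasis-specific"
        else:
            label = "primary-specific"
        rows[clone] = {"clone_class": label, "is_seeding": clone in seeding}
    return pd.DataFrame.from_dict(rows, orient="index")


def compute_ccd(
    profile: CloneCNProfile,
    include_clones: list[str] | None = None,
    length_weights: np.ndarray | None = None,
) -> float:
    """Clone copy number diversity: the tumour's maximal clone-pair distance.

    Concatenates the allele A and allele B copy-number vectors of each clone
    along the genome and returns the largest pairwise Euclidean distance.
    Clones found only in lymph nodes should be excluded by the caller via
    ``include_clones``; a single clone yields 0.
    """
    clones = [c for c in profile.clones if c != NORMAL_CLONE]
    if include_clones is not None:
        clones = [c for c in clones if c in set(include_clones)]
    if not clones:
        raise ValidationError("no clones left for CCD after exclusions")
    vectors = {}
    for c in clones:
        col = profile.column(c).astype(float)  # (m, 2)
        if length_weights is not None:
            col = col * np.sqrt(length_weights)[:, None]
        vectors[c] = col.T.ravel()  # allele A vector then allele B vector
    best = 0.0
    for a, b in combinations(clones, 2):
        best = max(best, float(np.linalg.norm(vectors[a] - vectors[b])))
    return best
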