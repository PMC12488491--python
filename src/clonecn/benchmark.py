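"""Evaluation metrics for clone copy-number reconstructions.

Three complementary views of agreement between a true and an inferred set of
clone profiles:

* ``accuracy`` — length-weighted Jaccard overlap of the distinct
  allele-specific states present in each segment (clone-label free);
* ``matched_clone_hd`` — for each true clone, the normalised Hamming
  distance to its closest predicted clone, averaged;
* ``tvd`` — total variation distance between the clone-proportion-weighted
  distributions over copy-number states, per segment and sample, averaged.
"""

from __future__ import annotations

import numpy as np

from .core import CloneCNProfile, CloneProportions, SegmentTable, ValidationError
from .tree import NORMAL_CLONE

__all__ = ["accuracy", "matched_clone_hd", "tvd", "state_distribution"]


def _tumour_states(profile: CloneCNProfile, seg_index: int) -> set[tuple[int, int]]:
    return {
        (int(profile.cA[seg_index, j]), int(profile.cB[seg_index, j]))
        for j, c in enumerate(profile.clones)
        if c != NORMAL_CLONE
    }


def accuracy(
    true: CloneCNProfile, pred: CloneCNProfile, segments: SegmentTable
) -> float:
    """Length-weighted mean Jaccard index of per-segment state sets."""
    missing = set(segments.segments) ^ (set(true.segments) & set(pred.segments) & set(segments.segments))
    if set(segments.segments) - set(true.segments) or set(segments.segments) - set(pred.segments):
        raise ValidationError("both profiles must cover every segment in the table")
    w = segments.lengths
    total = w.sum()
    acc = 0.0
    for i, seg in enumerate(segments.segments):
        s = _tumour_states(pred, pred.segments.index(seg))
        t = _tumour_states(true, true.segments.index(seg))
        acc += w[i] * len(s & t) / len(s | t)
    return acc / total


def matched_clone_hd(
    true: CloneCNProfile,
    pred: CloneCNProfile,
    length_weights: np.ndarray | None = None,
) -> float:
    """Mean best-match normalised Hamming distance over true clones.

    For each true tumour clone, the fraction of mismatching (segment, allele)
    entries against the closest predicted clone; matching is one-directional,
    so extra predicted clones cost nothing.  ``length_weights`` switches to a
    segment-length-weighted mismatch fraction.
    """
    if set(true.segments) != set(pred.segments):
        raise ValidationError("profiles cover different segments")
    order = [pred.segments.index(s) for s in true.segments]
    true_clones = [c for c in true.clones if c != NORMAL_CLONE]
    pred_clones = [c for c in pred.clones if c != NORMAL_CLONE]
    if not pred_clones:
        raise ValidationError("no predicted clones to match against")
    if length_weights is None:
        w = np.ones(len(true.segments))
    else:
        w = np.asarray(length_weights, dtype=float)
    w2 = np.concatenate([w, w])
    dists = []
    for tc in true_clones:
        tv = true.column(tc).T.ravel()
        best = np.inf
        for pc in pred_clones:
            pv = pred.column(pc)[order].T.ravel()
            d = float(w2[tv != pv].sum() / w2.sum())
            best = min(best, d)
        dists.append(best)
    return float(np.mean(dists))


def state_distribution(
    profile: CloneCNProfile,
    proportions: CloneProportions,
    seg_index: int,
    sample_index: int,
) -> dict[tuple[int, int], float]:
    """Distribution over allele-specific states among cancer cells.

    Tumour-clone proportions are renormalised by purity so the masses sum
    to 1 over cancer cells.
    """
    tumour = [c for c in profile.clones if c != NORMAL_CLONE]
    u = proportions.for_clones(tumour)[:, sample_index]
    mass = u.sum()
    if mass <= 0:
        raise ValidationError("sample contains no tumour cells")
    dist: dict[tuple[int, int], float] = {}
    for j, c in enumerate(tumour):
        state = (
            int(profile.cA[seg_index, profile.clones.index(c)]),
            int(profile.cB[seg_index, profile.clones.index(c)]),
        )
        dist[state] = dist.get(state, 0.0) + u[j] / mass
    return dist


def tvd(
    true: CloneCNProfile,
    true_proportions: CloneProportions,
    pred: CloneCNProfile,
    pred_proportions: CloneProportions,
) -> float:
    """Mean total variation distance between state distributions.

    Computed per segment and sample between the cancer-cell state
    distributions of the two reconstructions, then averaged.
    """
    if set(true.segments) != set(pred.segments):
        raise ValidationError("profiles cover different segments")
    if true_proportions.samples != pred_proportions.samples:
        raise ValidationError("proportion tables cover different samples")
    values = []
    for i, seg in enumerate(true.segments):
        pi = pred.segments.index(seg)
        for r in range(len(true_proportions.samples)):
            p = state_distribution(true, true_proportions, i, r)
            q = state_distribution(pred, pred_proportions, pi, r)
            states = set(p) | set(q)
            values.append(0.5 * sum(abs(p.get(s, 0.0) - q.get(s, 0.0)) for s in states))
    return float(np.mean(values))
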