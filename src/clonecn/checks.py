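"""Independent checkers for the evolutionary-model invariants.

These are deliberately written as plain traversals over the profile, with no
shared code with the MILP encoding, so that solver output can be verified
against the model rather than against itself.
"""

from __future__ import annotations

import numpy as np

from .core import CloneCNProfile, CloneProportions, FractionalCN, mixture_fractional
from .tree import CloneTree

__all__ = [
    "loh_persistence_ok",
    "path_sign_runs",
    "alternation_ok",
    "events_per_segment",
    "objective_values",
]


def _clone_state(profile: CloneCNProfile, clone: str, tree: CloneTree) -> np.ndarray:
    if clone == tree.root:
        return np.ones((len(profile.segments), 2), dtype=np.int64)
    return profile.column(clone)


def loh_persistence_ok(profile: CloneCNProfile, tree: CloneTree) -> bool:
    """True iff no allele at copy 0 in a parent is regained in any child."""
    for parent, child in tree.edges:
        cp = _clone_state(profile, parent, tree)
        cc = _clone_state(profile, child, tree)
        if ((cp == 0) & (cc > 0)).any():
            return False
    return True


def path_sign_runs(profile: CloneCNProfile, tree: CloneTree) -> np.ndarray:
    """Maximal same-sign runs of non-zero per-edge deltas on each root-to-node path.

    Returns an array of shape ``(n_tumour_clones, n_segments, 2)`` with the run
    count per terminal clone, segment and allele.  Zero deltas are transparent:
    a gain separated from an earlier gain only by unchanged edges continues the
    same run.
    """
    m = len(profile.segments)
    clones = tree.tumour_clones
    runs = np.zeros((len(clones), m, 2), dtype=np.int64)
    last = {}  # node -> (last_sign array, runs array)
    last[tree.root] = (np.zeros((m, 2), dtype=np.int64), np.zeros((m, 2), dtype=np.int64))
    for idx, clone in enumerate(clones):  # preorder: parents first
        parent = tree.parent(clone)
        sign_p, runs_p = last[parent]
        delta = _clone_state(profile, clone, tree) - _clone_state(profile, parent, tree)
        sign = np.sign(delta)
        new_run = (sign != 0) & (sign != sign_p)
        runs_c = runs_p + new_run
        sign_c = np.where(sign != 0, sign, sign_p)
        last[clone] = (sign_c, runs_c)
        runs[idx] = runs_c
    return runs


def alternation_ok(profile: CloneCNProfile, tree: CloneTree, bound: int = 2) -> bool:
    """True iff every root-to-node path has at most ``bound`` sign runs per allele."""
    return bool((path_sign_runs(profile, tree) <= bound).all())


def events_per_segment(profile: CloneCNProfile, tree: CloneTree) -> np.ndarray:
    """Total copy-number events ``sum_edges |dA| + |dB|`` per segment."""
    total = np.zeros(len(profile.segments), dtype=np.int64)
    for parent, child in tree.edges:
        delta = _clone_state(profile, child, tree) - _clone_state(profile, parent, tree)
        total += np.abs(delta).sum(axis=1)
    return total


def objective_values(
    profile: CloneCNProfile,
    proportions: CloneProportions,
    fractional: FractionalCN,
    per_allele: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Both model objectives per segment, computed from a finished profile.

    Returns ``(obj1, obj2)`` where ``obj1[s]`` counts samples whose predicted
    fractional copy number lies outside the observed interval for either
    allele (or counts (sample, allele) pairs when ``per_allele``), and
    ``obj2[s]`` is the Manhattan distance between predicted and observed
    fractional copy numbers summed over samples and alleles.
    """
    fA, fB = mixture_fractional(profile, proportions)
    pred = np.stack([fA, fB], axis=2)
    out = (pred < fractional.lo - 1e-9) | (pred > fractional.hi + 1e-9)
    if per_allele:
        obj1 = out.sum(axis=(1, 2))
    else:
        obj1 = out.any(axis=2).sum(axis=1)
    obj2 = np.abs(fractional.est - pred).sum(axis=(1, 2))
    return obj1.astype(np.int64), obj2
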