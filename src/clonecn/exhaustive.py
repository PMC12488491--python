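"""Exhaustive enumeration of clone labellings for small instances.

An independent reference for the MILP: enumerates every integer labelling of
the tumour clones up to ``c_max`` per allele, filters by the evolutionary
constraints (LOH persistence, path sign-run bound, homozygous-deletion
eligibility, event budget) and returns the lexicographic optimum of
(interval violations, Manhattan distance).  Exponential in clones; intended
for <= 5 tumour clones and small ``c_max``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .tree import CloneTree

__all__ = ["ExhaustiveResult", "enumerate_segment"]


@dataclass(frozen=True)
class ExhaustiveResult:
    clones: tuple[str, ...]
    cA: np.ndarray
    cB: np.ndarray
    objective1: int
    objective2: float
    events: int
    unique: bool  # no other feasible labelling attains the same objectives


def _allele_vectors(tree: CloneTree, c_max: int, run_bound: int):
    """All per-allele labellings respecting LOH persistence and the run bound."""
    clones = tree.tumour_clones
    n = len(clones)
    idx = {c: j for j, c in enumerate(clones)}
    parents = [-1 if tree.parent(c) == tree.root else idx[tree.parent(c)] for c in clones]
    vectors = []
    for combo in product(range(c_max + 1), repeat=n):
        ok = True
        sign_state = [0] * n
        runs = [0] * n
        for j, pj in enumerate(parents):
            parent_c = 1 if pj < 0 else combo[pj]
            if parent_c == 0 and combo[j] > 0:
                ok = False
                break
            d = combo[j] - parent_c
            s = (d > 0) - (d < 0)
            prev_sign = 0 if pj < 0 else sign_state[pj]
            prev_runs = 0 if pj < 0 else runs[pj]
            if s != 0 and s != prev_sign:
                runs[j] = prev_runs + 1
                sign_state[j] = s
            else:
                runs[j] = prev_runs
                sign_state[j] = prev_sign if s == 0 else s
            if runs[j] > run_bound:
                ok = False
                break
        if ok:
            vectors.append(combo)
    arr = np.array(vectors, dtype=np.int64)
    deltas = np.empty_like(arr)
    for j, pj in enumerate(parents):
        parent_c = 1 if pj < 0 else arr[:, pj]
        deltas[:, j] = arr[:, j] - parent_c
    events = np.abs(deltas).sum(axis=1)
    return arr, events


def enumerate_segment(
    tree: CloneTree,
    u: np.ndarray,            # (n, k) tumour clone proportions
    est: np.ndarray,          # (k, 2)
    lo: np.ndarray,
    hi: np.ndarray,
    lam: int,
    c_max: int = 4,
    run_bound: int = 2,
    eligible: np.ndarray | None = None,
    per_allele_obj1: bool = False,
) -> ExhaustiveResult:
    """Lexicographically optimal labelling of one segment by brute force."""
    clones = tuple(tree.tumour_clones)
    n = u.shape[0]
    if eligible is None:
        eligible = np.ones(n, dtype=bool)
    arr, events = _allele_vectors(tree, c_max, run_bound)
    V = len(arr)
    predA = arr @ u  # (V, k)
    outA = (predA < lo[None, :, 0] - 1e-9) | (predA > hi[None, :, 0] + 1e-9)
    outB = (predA < lo[None, :, 1] - 1e-9) | (predA > hi[None, :, 1] + 1e-9)
    devA = np.abs(predA - est[None, :, 0]).sum(axis=1)
    devB = np.abs(predA - est[None, :, 1]).sum(axis=1)
    zero = arr == 0

    best = None  # (obj1, obj2, ia, ib, ev)
    ties = 0
    for ia in range(V):
        ev_b_max = lam - events[ia]
        if ev_b_max < 0:
            continue
        mask = events <= ev_b_max
        if not mask.any():
            continue
        ib_all = np.flatnonzero(mask)
        # homozygous deletions only where eligible
        hom = zero[ia][None, :] & zero[ib_all]
        bad = (hom & ~eligible[None, :]).any(axis=1)
        ib_all = ib_all[~bad]
        if ib_all.size == 0:
            continue
        if per_allele_obj1:
            obj1 = outA[ia].sum() + outB[ib_all].sum(axis=1)
        else:
            obj1 = (outA[ia][None, :] | outB[ib_all]).sum(axis=1)
        obj2 = devA[ia] + devB[ib_all]
        order = np.lexsort((obj2, obj1))
        b = order[0]
        cand = (int(obj1[b]), float(obj2[b]), ia, int(ib_all[b]))
        if best is None or (cand[0], cand[1]) < (best[0], best[1] - 1e-12):
            best = cand
            # ties within this ia-block
            ties = int(
                ((obj1 == cand[0]) & (np.abs(obj2 - cand[1]) < 1e-9)).sum()
            ) - 1
        elif cand[0] == best[0] and abs(cand[1] - best[1]) < 1e-9:
            ties += int(((obj1 == cand[0]) & (np.abs(obj2 - cand[1]) < 1e-9)).sum())

    if best is None:
        raise ValueError("no feasible labelling under the given budget")
    obj1, obj2, ia, ib = best
    ev = int(events[ia] + events[ib])
    return ExhaustiveResult(
        clones, arr[ia].copy(), arr[ib].copy(), obj1, obj2, ev, unique=(ties == 0)
    )
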