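"""Model selection over the copy-number event budget.

The event budget (lambda) trades data fit against solution complexity: the
objective of the per-segment solve is non-increasing in lambda, and the best
budget sits at the elbow of that curve.  The elbow is located with the
Kneedle algorithm on the decreasing convex fit curve; when no knee exists the
selection falls back to parsimony rules described in `select_lambda`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["kneedle", "select_lambda", "sweep"]


def kneedle(
    x: Sequence[float],
    y: Sequence[float],
    sensitivity: float = 1.0,
) -> float | None:
    """Knee of a decreasing convex curve (Kneedle algorithm).

    Returns the x position of the first confirmed knee, or ``None`` when the
    curve has no knee (e.g. constant or linear curves).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return None
    x_span = x.max() - x.min()
    y_span = y.max() - y.min()
    if x_span <= 0 or y_span <= 0:
        return None
    xn = (x - x.min()) / x_span
    # flip the decreasing convex curve into an increasing concave one
    yn = (y.max() - y) / y_span
    diff = yn - xn
    # strict interior local maxima of the difference curve
    maxima = [
        i
        for i in range(1, len(diff) - 1)
        if diff[i] > diff[i - 1] and diff[i] >= diff[i + 1]
    ]
    if not maxima:
        return None
    threshold_drop = sensitivity * np.mean(np.diff(xn))
    for pos, i in enumerate(maxima):
        threshold = diff[i] - threshold_drop
        nxt = maxima[pos + 1] if pos + 1 < len(maxima) else len(diff)
        j = i + 1
        while j < len(diff):
            if j < nxt and diff[j] < threshold:
                return float(x[i])  # knee confirmed before the next local max
            if j >= nxt:
                break
            j += 1
        if pos + 1 == len(maxima) and diff[-1] < threshold:
            return float(x[i])
    return None


def select_lambda(
    lambdas: Sequence[int],
    objective2: Sequence[float],
    objective1: Sequence[int] | None = None,
    sensitivity: float = 1.0,
    min_drop: float = 0.0,
    tol: float = 1e-6,
) -> int:
    """Choose the event budget from a sweep curve.

    Kneedle locates the knee of the full objective-2 curve; the result is
    lower-bounded by ``lambda_base``, the smallest budget achieving the
    minimal objective 1 (interval violations), which acts as the primary
    filter.  A knee beyond ``lambda_base`` is accepted only when the mean
    objective-2 improvement per added event from ``lambda_base`` to the knee
    is at least ``min_drop``; smaller improvements are within measurement
    noise and the parsimonious ``lambda_base`` is returned.  When no knee
    exists, the smallest budget within ``tol`` of the minimal objective 2 is
    returned if the curve's per-event improvement is material, otherwise
    ``lambda_base``.
    """
    lambdas = list(lambdas)
    obj2 = np.asarray(objective2, dtype=float)
    if len(lambdas) != len(obj2) or not lambdas:
        raise ValueError("lambdas and objective2 must be equal-length, non-empty")
    if objective1 is not None:
        obj1 = np.asarray(objective1)
        base = int(np.flatnonzero(obj1 == obj1.min())[0])
    else:
        base = 0
    lam_base = lambdas[base]
    finite = np.isfinite(obj2)
    if len(lambdas) < 2 or not finite.all() or obj2.max() - obj2.min() <= tol:
        return lam_base
    knee = kneedle(lambdas, obj2, sensitivity=sensitivity)
    if knee is None:
        # linear-ish curve with no knee anywhere
        xs, ys = lambdas[base:], obj2[base:]
        total_steps = xs[-1] - lam_base
        if total_steps > 0 and (ys[0] - ys.min()) / total_steps >= min_drop:
            good = np.flatnonzero(ys <= ys.min() + tol)
            return xs[int(good[0])]
        return lam_base
    lam_knee = max(int(knee), lam_base)
    if lam_knee == lam_base:
        return lam_base
    drop = obj2[base] - obj2[lambdas.index(lam_knee)]
    return lam_knee if drop / (lam_knee - lam_base) >= min_drop else lam_base


def sweep(
    solve: Callable[[int], object],
    lambda_max: int,
    patience: int = 3,
    improvement_tol: float = 0.0,
    score: Callable[[object], float] | None = None,
    selector: Callable[[list], int] | None = None,
) -> list:
    """Run ``solve`` for budgets 0..lambda_max with early stopping.

    Stops when a perfect fit is reached; when the combined objective has not
    improved by more than ``improvement_tol`` for ``patience`` consecutive
    budgets; or -- if a ``selector`` (the model-selection rule applied to the
    partial curve) is supplied -- once the selected budget has been stable
    for ``patience`` consecutive extensions of the curve and the sweep has
    explored ``patience`` budgets past it.  Returns the per-budget solutions.
    """
    if score is None:
        score = lambda sol: float(getattr(sol, "combined_objective"))
    solutions = []
    best = np.inf
    stale = 0
    last_sel: int | None = None
    sel_stable = 0
    for lam in range(0, lambda_max + 1):
        sol = solve(lam)
        solutions.append(sol)
        val = score(sol)
        if val < best - improvement_tol:
            best = val
            stale = 0
        else:
            stale += 1
        if val <= 1e-9:
            break
        if stale >= patience:
            break
        if selector is not None and len(solutions) >= 2:
            sel = selector(solutions)
            sel_stable = sel_stable + 1 if sel == last_sel else 1
            last_sel = sel
            if sel_stable >= patience and lam >= sel + patience:
                break
    return solutions
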