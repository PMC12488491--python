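"""Per-segment mixed-integer inference of clone copy numbers.

Each genomic segment is solved independently.  Given the clone tree, the
clone proportions and the observed allele-specific fractional copy numbers
with interval bounds, the solver searches integer clone states that

1. minimise the number of samples whose predicted mixture
   ``sum_i c_i u_i`` falls outside the observed interval for either allele,
2. among those, minimise the Manhattan distance between predicted and
   observed fractional copy numbers,

subject to the evolutionary model: the diploid root is (1,1); loss of
heterozygosity is irreversible along descent; the number of gain/loss sign
runs on any root-to-node path is bounded (default 2 per allele); homozygous
deletions are only allowed where eligible; and the total number of unit
copy-number events across edges and alleles is at most the budget ``lambda``.

The lexicographic order is enforced with two solver stages: the first
minimises the violation count, the second minimises the Manhattan distance
with the violation count capped at the stage-1 optimum.  The budget is swept
upwards and the final budget is chosen by elbow-based model selection (see
`clonecn.model_select`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .checks import alternation_ok, loh_persistence_ok
from .core import (
    CloneCNProfile,
    CloneProportions,
    FractionalCN,
    SegmentTable,
    ValidationError,
)
from .model_select import select_lambda, sweep
from .preprocess import HomDelEligibility
from .tree import CloneTree, NORMAL_CLONE

__all__ = ["SolverOptions", "SegmentSolution", "solve_segment", "sweep_lambda",
           "infer_tumour", "auto_c_max"]


@dataclass(frozen=True)
class SolverOptions:
    """Tunable parameters of the per-segment solver.

    c_max            per-allele copy-number ceiling; "auto" derives it per
                     segment from the observed upper bounds and the smallest
                     positive clone proportion.
    c_max_cap / tau  cap and proportion floor used by the auto rule.
    run_bound        maximal number of same-sign runs of per-edge changes on
                     any root-to-node path, per allele (default 2: one type of
                     change may recur, the other may appear once).
    lambda_max       largest event budget swept; None = 4 * number of edges.
    patience         sweep stops after this many budgets without material
                     improvement.
    elbow_sensitivity  Kneedle sensitivity.
    knee_min_drop    minimal mean objective-2 improvement per added event for
                     a knee to be accepted; "auto" = half the mean half-width
                     of the observed intervals at 4 samples, scaled with
                     sqrt(n_samples) (improvements within the measurement
                     noise are not evidence of real events).
    mip_gap / time_limit  passed to the MILP backend; gap 0 gives provably
                     exact optima.
    per_allele_obj1  count (sample, allele) violations instead of samples.
    """

    c_max: int | str = "auto"
    c_max_cap: int = 40
    tau: float = 0.05
    run_bound: int = 2
    lambda_max: int | None = None
    patience: int = 3
    elbow_sensitivity: float = 1.0
    knee_min_drop: float | str = "auto"
    mip_gap: float = 1e-6
    time_limit: float | None = 60.0
    per_allele_obj1: bool = False
    seed: int | None = None

    def __post_init__(self):
        if isinstance(self.c_max, int) and self.c_max < 1:
            raise ValidationError("c_max must be >= 1")
        if self.run_bound < 1:
            raise ValidationError("run_bound must be >= 1")


@dataclass(frozen=True)
class SegmentSolution:
    """Solver output for one segment at one event budget."""

    clones: tuple[str, ...]          # tumour clones, preorder
    cA: np.ndarray
    cB: np.ndarray
    objective1: int                  # samples (or sample-alleles) out of bounds
    objective2: float                # Manhattan distance to the estimates
    events: int                      # sum over edges and alleles of |delta|
    lam: int
    status: str = "optimal"

    @property
    def combined_objective(self) -> float:
        # for sweep bookkeeping only; the solver uses its own exact weight
        return self.objective1 * 1e6 + self.objective2


def auto_c_max(hi: np.ndarray, u: np.ndarray, cap: int = 40, tau: float = 0.05) -> int:
    """Per-segment copy-number ceiling.

    Chosen so that a subclonal amplification large enough to explain the
    largest observed upper bound through the smallest (floored) positive clone
    proportion remains representable, while keeping the search bounded.
    """
    pos = u[u > 0]
    floor = max(tau, float(pos.min()) if pos.size else tau)
    needed = int(math.ceil(float(hi.max()) / floor)) if hi.size else 1
    return max(2, min(cap, needed))


class _SegmentModel:
    """MILP encoding for one segment; reused across the budget sweep.

    Variable layout (n tumour clones in preorder, k samples); X ranges over
    the two alleles:

    ======================  ======================  ==========
    block                   meaning                 type
    ======================  ======================  ==========
    cX[j]                   clone copy number       integer [0, c_max]
    zX[j]                   cX[j] == 0 indicator    binary
    posX[j], negX[j]        edge delta split        continuous
    gX[j], lX[j]            gain / loss on edge     binary
    sGX[j], sLX[j]          last sign on root path  continuous in {0,1}
    pXab[j]                 linearised products     continuous in {0,1}
    rX[j]                   sign runs on root path  continuous [0, run_bound]
    v[r]                    sample out of bounds    binary
    devX[r]                 |f_hat - prediction|    continuous
    ======================  ======================  ==========

    ``sGX``/``sLX`` and the products are forced to integer values by their
    defining equalities, so only c, z, g, l and v need integrality.
    """

    def __init__(
        self,
        tree: CloneTree,
        u: np.ndarray,              # (n, k) tumour clone proportions
        est: np.ndarray,            # (k, 2)
        lo: np.ndarray,
        hi: np.ndarray,
        eligible: np.ndarray,       # (n,) bool, homozygous-deletion eligibility
        options: SolverOptions,
        structural: bool = True,
    ):
        self.structural = structural
        self.tree = tree
        self.clones = tree.tumour_clones
        self.u = u
        self.est, self.lo, self.hi = est, lo, hi
        self.eligible = np.asarray(eligible, dtype=bool)
        self.options = options
        n, k = len(self.clones), u.shape[1]
        self.n, self.k = n, k
        if isinstance(options.c_max, str):
            cmax = auto_c_max(hi, u, cap=options.c_max_cap, tau=options.tau)
            # per-clone refinement of the ceiling: a clone's copy number can
            # only be supported by the data up to the largest observed upper
            # bound divided by its maximal (floored) prevalence
            u_max = u.max(axis=1)
            per_clone = np.ceil(float(hi.max()) / np.maximum(u_max, options.tau))
            ub_c = np.clip(per_clone, 2, cmax).astype(np.int64)
            ub_c[u_max == 0] = cmax
        else:
            cmax = options.c_max
            ub_c = np.full(len(self.clones), cmax, dtype=np.int64)
        self.c_max = cmax
        self.ub_c = ub_c

        idx = {c: j for j, c in enumerate(self.clones)}
        self.parent = [
            -1 if tree.parent(c) == tree.root else idx[tree.parent(c)] for c in self.clones
        ]

        # ---- variable offsets -------------------------------------------
        def block(size):
            nonlocal nv
            start = nv
            nv += size
            return start

        nv = 0
        self.i_c = [block(n), block(n)]          # cA, cB
        self.i_pos = [block(n), block(n)]
        self.i_neg = [block(n), block(n)]
        if structural:
            self.i_z = [block(n), block(n)]
            self.i_g = [block(n), block(n)]
            self.i_l = [block(n), block(n)]
            self.i_sG = [block(n), block(n)]
            self.i_sL = [block(n), block(n)]
            self.i_pGG = [block(n), block(n)]    # g[j] * sG[parent]
            self.i_pLG = [block(n), block(n)]    # l[j] * sG[parent]
            self.i_pGL = [block(n), block(n)]    # g[j] * sL[parent]
            self.i_pLL = [block(n), block(n)]    # l[j] * sL[parent]
            self.i_r = [block(n), block(n)]
        self.i_v = block(k)
        self.i_dev = [block(k), block(k)]
        self.nv = nv

        lb = np.zeros(nv)
        ub = np.ones(nv)
        integrality = np.zeros(nv)
        parent_ub = np.array(
            [1 if pj < 0 else ub_c[pj] for pj in self.parent], dtype=float
        )
        for a in range(2):
            ub[self.i_c[a]:self.i_c[a] + n] = ub_c
            integrality[self.i_c[a]:self.i_c[a] + n] = 1
            ub[self.i_pos[a]:self.i_pos[a] + n] = ub_c
            ub[self.i_neg[a]:self.i_neg[a] + n] = parent_ub
            if structural:
                for blk in (self.i_z, self.i_g, self.i_l):
                    integrality[blk[a]:blk[a] + n] = 1
                ub[self.i_r[a]:self.i_r[a] + n] = options.run_bound
            ub[self.i_dev[a]:self.i_dev[a] + k] = np.inf
        integrality[self.i_v:self.i_v + k] = 1
        self.bounds = Bounds(lb, ub)
        self.integrality = integrality

        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        con_lb: list[float] = []
        con_ub: list[float] = []
        self._row = 0

        def add(entries, lo_, hi_):
            for col, val in entries:
                rows.append(self._row)
                cols.append(col)
                vals.append(val)
            con_lb.append(lo_)
            con_ub.append(hi_)
            self._row += 1

        M = cmax + float(hi.max()) + 1.0
        for a in range(2):
            c0 = self.i_c[a]
            p0, q0 = self.i_pos[a], self.i_neg[a]
            for j in range(n):
                pj = self.parent[j]
                # delta definition: c[j] - c[parent] = pos - neg
                ent = [(c0 + j, 1.0), (p0 + j, -1.0), (q0 + j, 1.0)]
                if pj >= 0:
                    ent.append((c0 + pj, -1.0))
                    add(ent, 0.0, 0.0)
                else:
                    add(ent, 1.0, 1.0)
        for a in range(2) if structural else ():
            c0, z0 = self.i_c[a], self.i_z[a]
            p0, q0 = self.i_pos[a], self.i_neg[a]
            g0, l0 = self.i_g[a], self.i_l[a]
            sg0, sl0 = self.i_sG[a], self.i_sL[a]
            gg0, lg0 = self.i_pGG[a], self.i_pLG[a]
            gl0, ll0 = self.i_pGL[a], self.i_pLL[a]
            r0 = self.i_r[a]
            for j in range(n):
                pj = self.parent[j]
                ubj = float(ub_c[j])
                ubp = float(parent_ub[j])
                # zero indicator: c + ub*z <= ub ; c + z >= 1
                add([(c0 + j, 1.0), (z0 + j, ubj)], -np.inf, ubj)
                add([(c0 + j, 1.0), (z0 + j, 1.0)], 1.0, np.inf)
                # LOH persistence: z[parent] <= z[j]
                if pj >= 0:
                    add([(z0 + pj, 1.0), (z0 + j, -1.0)], -np.inf, 0.0)
                # gain/loss indicators tied to the delta split
                add([(p0 + j, 1.0), (g0 + j, -ubj)], -np.inf, 0.0)
                add([(g0 + j, 1.0), (p0 + j, -1.0)], -np.inf, 0.0)
                add([(q0 + j, 1.0), (l0 + j, -ubp)], -np.inf, 0.0)
                add([(l0 + j, 1.0), (q0 + j, -1.0)], -np.inf, 0.0)
                add([(g0 + j, 1.0), (l0 + j, 1.0)], -np.inf, 1.0)
                if pj >= 0:
                    # products with the parent's sign state
                    for prod0, a0, b0 in (
                        (gg0, g0 + j, sg0 + pj),
                        (lg0, l0 + j, sg0 + pj),
                        (gl0, g0 + j, sl0 + pj),
                        (ll0, l0 + j, sl0 + pj),
                    ):
                        add([(prod0 + j, 1.0), (a0, -1.0)], -np.inf, 0.0)
                        add([(prod0 + j, 1.0), (b0, -1.0)], -np.inf, 0.0)
                        add([(prod0 + j, 1.0), (a0, -1.0), (b0, -1.0)], -1.0, np.inf)
                    # sign-state recursions
                    add(
                        [(sg0 + j, 1.0), (g0 + j, -1.0), (sg0 + pj, -1.0),
                         (gg0 + j, 1.0), (lg0 + j, 1.0)],
                        0.0, 0.0,
                    )
                    add(
                        [(sl0 + j, 1.0), (l0 + j, -1.0), (sl0 + pj, -1.0),
                         (ll0 + j, 1.0), (gl0 + j, 1.0)],
                        0.0, 0.0,
                    )
                    # run counter: r[j] = r[parent] + g - g*sG[par] + l - l*sL[par]
                    add(
                        [(r0 + j, 1.0), (r0 + pj, -1.0), (g0 + j, -1.0),
                         (gg0 + j, 1.0), (l0 + j, -1.0), (ll0 + j, 1.0)],
                        0.0, 0.0,
                    )
                else:
                    # the root carries no sign state: products vanish
                    for prod0 in (gg0, lg0, gl0, ll0):
                        add([(prod0 + j, 1.0)], 0.0, 0.0)
                    add([(sg0 + j, 1.0), (g0 + j, -1.0)], 0.0, 0.0)
                    add([(sl0 + j, 1.0), (l0 + j, -1.0)], 0.0, 0.0)
                    add([(r0 + j, 1.0), (g0 + j, -1.0), (l0 + j, -1.0)], 0.0, 0.0)
        # homozygous deletions only where eligible
        if structural:
            for j in range(n):
                if not eligible[j]:
                    add([(self.i_z[0] + j, 1.0), (self.i_z[1] + j, 1.0)], -np.inf, 1.0)
        # interval violations and deviations per sample and allele
        for a in range(2):
            for r in range(k):
                mix = [(self.i_c[a] + j, float(u[j, r])) for j in range(n) if u[j, r] != 0]
                add(mix + [(self.i_v + r, M)], float(lo[r, a]), np.inf)
                add(mix + [(self.i_v + r, -M)], -np.inf, float(hi[r, a]))
                add(mix + [(self.i_dev[a] + r, 1.0)], float(est[r, a]), np.inf)
                add([(col, -val) for col, val in mix] + [(self.i_dev[a] + r, 1.0)],
                    -float(est[r, a]), np.inf)
        # event budget; right-hand side replaced at each sweep step
        budget = []
        for a in range(2):
            for j in range(n):
                budget.append((self.i_pos[a] + j, 1.0))
                budget.append((self.i_neg[a] + j, 1.0))
        add(budget, 0.0, 0.0)
        self.budget_row = self._row - 1
        # violation budget for the second lexicographic stage
        add([(self.i_v + r, 1.0) for r in range(k)], 0.0, float(k))
        self.viol_row = self._row - 1

        self.A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self._row, nv)
        )
        self.con_lb = np.array(con_lb)
        self.con_ub = np.array(con_ub)

        # equivalent single-objective weight, used only for sweep bookkeeping
        self.weight = 1.0 + float(np.maximum(est, cmax).sum())
        obj1_vec = np.zeros(nv)
        obj1_vec[self.i_v:self.i_v + k] = 1.0
        obj2_vec = np.zeros(nv)
        obj2_vec[self.i_dev[0]:self.i_dev[0] + k] = 1.0
        obj2_vec[self.i_dev[1]:self.i_dev[1] + k] = 1.0
        self.obj1_vec = obj1_vec
        self.obj2_vec = obj2_vec
        self._zero_violations_from: int | None = None

    def feasible_full(self, cA: np.ndarray, cB: np.ndarray) -> bool:
        """Does a labelling satisfy the structural constraints of the model?"""
        if ((cA == 0) & (cB == 0) & ~self.eligible).any():
            return False
        return _solution_invariants_ok(
            self.tree, self.clones, cA, cB, self.options.run_bound
        )

    def _milp(self, c, ub):
        opts = {"presolve": True, "mip_rel_gap": self.options.mip_gap}
        if self.options.time_limit is not None:
            opts["time_limit"] = self.options.time_limit
        constraints = LinearConstraint(self.A, self.con_lb, ub)
        res = milp(
            c=c, constraints=constraints, integrality=self.integrality,
            bounds=self.bounds, options=opts,
        )
        if res.x is None and res.status == 4:
            # occasional backend solve error with presolve on; retry without
            opts["presolve"] = False
            res = milp(
                c=c, constraints=constraints, integrality=self.integrality,
                bounds=self.bounds, options=opts,
            )
        return res

    def solve(self, lam: int) -> SegmentSolution:
        """Exact lexicographic solve at one budget (two stages).

        Stage 1 minimises the number of out-of-interval samples; stage 2
        minimises the Manhattan distance with the violation count capped at
        the stage-1 optimum.  Budget 0 forces the all-diploid labelling, and
        once stage 1 reaches zero violations it stays there for every larger
        budget (the feasible set only grows), so it is not re-solved.
        """
        if lam == 0:
            ones = np.ones(self.n, dtype=np.int64)
            return self.evaluate(ones, ones.copy(), lam, "optimal")
        ub = self.con_ub.copy()
        ub[self.budget_row] = float(lam)
        if self._zero_violations_from is not None and lam >= self._zero_violations_from:
            nviol = 0
        else:
            res1 = self._milp(self.obj1_vec, ub)
            if res1.x is None:
                return self._failed(lam, res1.message)
            nviol = int(round(res1.fun))
            if nviol == 0:
                self._zero_violations_from = lam
        ub[self.viol_row] = float(nviol)
        res = self._milp(self.obj2_vec, ub)
        if res.x is None:
            return self._failed(lam, res.message)
        cA = np.rint(res.x[self.i_c[0]:self.i_c[0] + self.n]).astype(np.int64)
        cB = np.rint(res.x[self.i_c[1]:self.i_c[1] + self.n]).astype(np.int64)
        status = "optimal" if res.status == 0 else f"status{res.status}"
        return self.evaluate(cA, cB, lam, status)

    def _failed(self, lam: int, message: str) -> SegmentSolution:
        return SegmentSolution(
            tuple(self.clones),
            np.ones(self.n, dtype=np.int64),
            np.ones(self.n, dtype=np.int64),
            objective1=self.k,
            objective2=float("inf"),
            events=0,
            lam=lam,
            status=f"failed:{message}",
        )

    def evaluate(self, cA: np.ndarray, cB: np.ndarray, lam: int, status: str) -> SegmentSolution:
        """Score a candidate labelling independently of the solver state."""
        obj1, obj2 = _segment_objectives(
            cA, cB, self.u, self.est, self.lo, self.hi, self.options.per_allele_obj1
        )
        events = 0
        for c in (cA, cB):
            for j, pj in enumerate(self.parent):
                parent_c = 1 if pj < 0 else c[pj]
                events += abs(int(c[j]) - int(parent_c))
        return SegmentSolution(
            tuple(self.clones), cA, cB, obj1, obj2, events, lam, status
        )


def _integer_partitions(w: int):
    """Partitions of w into positive parts, e.g. 3 -> [3], [2,1], [1,1,1]."""
    if w == 0:
        yield ()
        return
    def rec(remaining, maxpart):
        if remaining == 0:
            yield ()
            return
        for p in range(min(remaining, maxpart), 0, -1):
            for rest in rec(remaining - p, p):
                yield (p,) + rest
    yield from rec(w, w)


class _EnumContext:
    """Tumour-level tables for enumeration of small event budgets.

    For each total event weight w, enumerates every assignment of net integer
    changes to (edge) slots of one allele with ``sum |delta| = w``, keeps
    those satisfying LOH persistence and the sign-run bound, and precomputes
    the implied clone copy numbers and per-sample mixture predictions.  These
    depend only on the tree and the clone proportions, so they are shared by
    all segments of a tumour.
    """

    def __init__(self, tree: CloneTree, u: np.ndarray, options: SolverOptions,
                 max_budget: int = 4):
        from itertools import combinations, permutations, product

        clones = tree.tumour_clones
        idx = {c: j for j, c in enumerate(clones)}
        parent = [
            -1 if tree.parent(c) == tree.root else idx[tree.parent(c)] for c in clones
        ]
        n = len(clones)
        self.n = n
        self.max_budget = max_budget
        # P[j, e] = 1 iff edge e (leading into clone e) lies on root->j path
        P = np.zeros((n, n), dtype=np.int64)
        for j in range(n):
            e = j
            while e >= 0:
                P[j, e] = 1
                e = parent[e]

        run_bound = options.run_bound
        self.by_weight: dict[int, dict[str, np.ndarray]] = {}
        for w in range(0, max_budget + 1):
            blocks = []
            for part in _integer_partitions(w):
                k_parts = len(part)
                if k_parts == 0:
                    blocks.append(np.zeros((1, n), dtype=np.int64))
                    continue
                if k_parts > n:
                    continue
                slots = np.array(list(combinations(range(n), k_parts)), dtype=np.int64)
                rows = np.arange(len(slots))[:, None]
                for perm in set(permutations(part)):
                    for signs in product((1, -1), repeat=k_parts):
                        vals = np.array([m * s for m, s in zip(perm, signs)], dtype=np.int64)
                        block = np.zeros((len(slots), n), dtype=np.int64)
                        block[rows, slots] = vals
                        blocks.append(block)
            D = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, n), np.int64)
            C = 1 + D @ P.T  # (N, n) clone copy numbers implied by the deltas
            ok = (C >= 0).all(axis=1)
            # LOH persistence on every edge
            for j in range(n):
                pj = parent[j]
                if pj >= 0:
                    ok &= ~((C[:, pj] == 0) & (C[:, j] > 0))
            # sign-run bound along every root-to-node path
            if w >= 2:
                runs = np.zeros((len(D), n), dtype=np.int64)
                sign_state = np.zeros((len(D), n), dtype=np.int64)
                for j in range(n):  # preorder: parent index < j
                    pj = parent[j]
                    s = np.sign(D[:, j])
                    prev_sign = sign_state[:, pj] if pj >= 0 else 0
                    prev_runs = runs[:, pj] if pj >= 0 else 0
                    new_run = (s != 0) & (s != prev_sign)
                    runs[:, j] = prev_runs + new_run
                    sign_state[:, j] = np.where(s != 0, s, prev_sign)
                ok &= (runs <= run_bound).all(axis=1)
            C = C[ok]
            self.by_weight[w] = {
                "C": C,
                "zero": C == 0,
                "cmax": C.max(axis=1) if len(C) else np.zeros(0, np.int64),
                "pred": C @ u,  # (N, k)
            }


class _EnumSolver:
    """Exact solve of small budgets from precomputed enumeration tables.

    Per segment, candidates are filtered by the per-clone ceiling and the
    objectives evaluated vectorised over all pairs of allele assignments
    within the budget.  Equivalent to the MILP for budgets up to the
    context's maximum, but orders of magnitude faster.
    """

    def __init__(self, context: _EnumContext, est, lo, hi, eligible, options, ub_c):
        self.context = context
        self.options = options
        self.eligible = np.asarray(eligible, dtype=bool)
        self.max_budget = context.max_budget
        self.tables = {}
        for w, tab in context.by_weight.items():
            keep = (tab["C"] <= ub_c[None, :]).all(axis=1)
            C = tab["C"][keep]
            pred = tab["pred"][keep]
            self.tables[w] = {
                "C": C,
                "zero": tab["zero"][keep],
                "devA": np.abs(pred - est[None, :, 0]).sum(axis=1),
                "devB": np.abs(pred - est[None, :, 1]).sum(axis=1),
                "outA": (pred < lo[None, :, 0] - 1e-9) | (pred > hi[None, :, 0] + 1e-9),
                "outB": (pred < lo[None, :, 1] - 1e-9) | (pred > hi[None, :, 1] + 1e-9),
            }

    def solve(self, lam: int, evaluate) -> SegmentSolution:
        per_allele = self.options.per_allele_obj1
        best = None  # (obj1, obj2, wa, ia, wb, ib)
        inelig = ~self.eligible
        for wa in range(0, min(lam, self.max_budget) + 1):
            A = self.tables[wa]
            if not len(A["C"]):
                continue
            for wb in range(0, min(lam - wa, self.max_budget) + 1):
                B = self.tables[wb]
                if not len(B["C"]):
                    continue
                obj2 = A["devA"][:, None] + B["devB"][None, :]
                if per_allele:
                    obj1 = A["outA"].sum(axis=1)[:, None] + B["outB"].sum(axis=1)[None, :]
                else:
                    obj1 = (A["outA"][:, None, :] | B["outB"][None, :, :]).sum(axis=2)
                if inelig.any():
                    bad = (A["zero"][:, None, :] & B["zero"][None, :, :] & inelig).any(axis=2)
                    obj1 = np.where(bad, np.iinfo(np.int64).max // 2, obj1)
                flat = np.lexsort((obj2.ravel(), obj1.ravel()))[0]
                ia, ib = np.unravel_index(flat, obj2.shape)
                cand = (int(obj1[ia, ib]), float(obj2[ia, ib]), wa, int(ia), wb, int(ib))
                if best is None or (cand[0], cand[1]) < (best[0], best[1] - 1e-12):
                    best = cand
        _, _, wa, ia, wb, ib = best
        cA = self.tables[wa]["C"][ia]
        cB = self.tables[wb]["C"][ib]
        return evaluate(cA.copy(), cB.copy(), lam, "optimal")


class _TieredModel:
    """Exact two-tier solve of one segment.

    The structural constraints (LOH persistence, sign-run bound, homozygous-
    deletion eligibility) are first dropped, which removes all the indicator
    binaries and makes the MILP far smaller.  If the relaxed optimum already
    satisfies them -- the overwhelmingly common case -- it is the optimum of
    the full model, since relaxing constraints can only improve the optimum.
    Otherwise the full encoding is solved.
    """

    ENUM_MAX_BUDGET = 4
    ENUM_MAX_CLONES = 20

    def __init__(self, tree, u, est, lo, hi, eligible, options, enum_context=None):
        self.relaxed = _SegmentModel(tree, u, est, lo, hi, eligible, options, structural=False)
        self._full: _SegmentModel | None = None
        self._enum: _EnumSolver | None = None
        self._enum_context = enum_context
        self._args = (tree, u, est, lo, hi, eligible, options)

    @property
    def weight(self) -> float:
        return self.relaxed.weight

    @property
    def c_max(self) -> int:
        return self.relaxed.c_max

    @property
    def tree(self):
        return self.relaxed.tree

    @property
    def clones(self):
        return self.relaxed.clones

    @property
    def parent(self):
        return self.relaxed.parent

    def evaluate(self, cA, cB, lam, status):
        return self.relaxed.evaluate(cA, cB, lam, status)

    def solve(self, lam: int) -> SegmentSolution:
        n = len(self.relaxed.clones)
        if 0 < lam <= self.ENUM_MAX_BUDGET and n <= self.ENUM_MAX_CLONES:
            if self._enum is None:
                tree, u, est, lo, hi, eligible, options = self._args
                if self._enum_context is None:
                    self._enum_context = _EnumContext(
                        tree, u, options, max_budget=self.ENUM_MAX_BUDGET
                    )
                self._enum = _EnumSolver(
                    self._enum_context, est, lo, hi, eligible, options,
                    self.relaxed.ub_c,
                )
            sol = self._enum.solve(lam, self.relaxed.evaluate)
            if sol.objective1 == 0 and self.relaxed._zero_violations_from is None:
                # the relaxed stage-1 optimum can only be lower; skip it later
                self.relaxed._zero_violations_from = lam
            return sol
        sol = self.relaxed.solve(lam)
        if sol.status.startswith("failed") or self.relaxed.feasible_full(sol.cA, sol.cB):
            return sol
        if self._full is None:
            self._full = _SegmentModel(*self._args, structural=True)
        return self._full.solve(lam)


def _segment_objectives(cA, cB, u, est, lo, hi, per_allele=False) -> tuple[int, float]:
    pred = np.stack([cA @ u, cB @ u], axis=1)  # (k, 2)
    out = (pred < lo - 1e-9) | (pred > hi + 1e-9)
    obj1 = int(out.sum()) if per_allele else int(out.any(axis=1).sum())
    obj2 = float(np.abs(est - pred).sum())
    return obj1, obj2


def _segment_arrays(
    tree: CloneTree,
    proportions: CloneProportions,
    fractional: FractionalCN,
    eligibility: HomDelEligibility | None,
    seg_index: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    clones = tree.tumour_clones
    u = proportions.for_clones(clones)
    est = fractional.est[seg_index]
    lo = fractional.lo[seg_index]
    hi = fractional.hi[seg_index]
    if eligibility is None:
        eligible = np.ones(len(clones), dtype=bool)
    else:
        seg = fractional.segments[seg_index]
        i = eligibility.segments.index(seg)
        eligible = np.array(
            [eligibility.eligible[i, eligibility.clones.index(c)] for c in clones]
        )
    return u, est, lo, hi, eligible


def solve_segment(
    lam: int,
    tree: CloneTree,
    proportions: CloneProportions,
    fractional: FractionalCN,
    segment: str,
    eligibility: HomDelEligibility | None = None,
    options: SolverOptions | None = None,
) -> SegmentSolution:
    """Solve one segment at a fixed event budget."""
    options = options or SolverOptions()
    seg_index = fractional.segments.index(segment)
    u, est, lo, hi, eligible = _segment_arrays(
        tree, proportions, fractional, eligibility, seg_index
    )
    model = _TieredModel(tree, u, est, lo, hi, eligible, options)
    return model.solve(lam)


def _material_drop(lo: np.ndarray, hi: np.ndarray, options: SolverOptions) -> float:
    """Smallest objective-2 improvement per event treated as evidence.

    Tied to the stated measurement uncertainty (the interval half-width) and
    scaled with the square root of the sample count: the best spurious
    single-event improvement grows with the number of per-sample residuals
    available to chase.
    """
    if options.knee_min_drop == "auto":
        k = lo.shape[0]
        return 0.25 * float(np.mean((hi - lo) / 2.0)) * math.sqrt(k)
    return float(options.knee_min_drop)


def sweep_lambda(
    tree: CloneTree,
    proportions: CloneProportions,
    fractional: FractionalCN,
    segment: str,
    eligibility: HomDelEligibility | None = None,
    options: SolverOptions | None = None,
) -> list[SegmentSolution]:
    """Sweep the event budget upwards for one segment (with early stopping)."""
    options = options or SolverOptions()
    seg_index = fractional.segments.index(segment)
    u, est, lo, hi, eligible = _segment_arrays(
        tree, proportions, fractional, eligibility, seg_index
    )
    model = _TieredModel(tree, u, est, lo, hi, eligible, options)
    lambda_max = options.lambda_max
    if lambda_max is None:
        lambda_max = 4 * len(tree.edges)
    imp_tol = _material_drop(lo, hi, options)
    return sweep(
        model.solve,
        lambda_max,
        patience=options.patience,
        improvement_tol=imp_tol,
        score=lambda s: s.objective1 * model.weight + s.objective2,
        selector=_make_selector(options, imp_tol),
    )


def _make_selector(options: SolverOptions, imp_tol: float):
    def selector(solutions):
        return select_lambda(
            [s.lam for s in solutions],
            [s.objective2 for s in solutions],
            objective1=[s.objective1 for s in solutions],
            sensitivity=options.elbow_sensitivity,
            min_drop=imp_tol,
        )

    return selector


def _canonicalize_extinct(
    model: _SegmentModel,
    solution: SegmentSolution,
    u: np.ndarray,
    run_bound: int,
) -> SegmentSolution:
    """Give data-unconstrained clones (u == 0 everywhere) their parent's state.

    Applied only when the reassignment keeps every model invariant and both
    objective values unchanged.
    """
    extinct = np.flatnonzero((u == 0).all(axis=1))
    if extinct.size == 0:
        return solution
    cA, cB = solution.cA.copy(), solution.cB.copy()
    tree = model.tree
    clones = list(solution.clones)
    for j in extinct:
        pj = model.parent[j]
        pa = 1 if pj < 0 else cA[pj]
        pb = 1 if pj < 0 else cB[pj]
        if cA[j] == pa and cB[j] == pb:
            continue
        trialA, trialB = cA.copy(), cB.copy()
        trialA[j], trialB[j] = pa, pb
        cand = model.evaluate(trialA, trialB, solution.lam, solution.status)
        if (
            cand.objective1 == solution.objective1
            and abs(cand.objective2 - solution.objective2) < 1e-9
            and cand.events <= solution.lam
            and _solution_invariants_ok(tree, clones, trialA, trialB, run_bound)
        ):
            cA, cB = trialA, trialB
    final = model.evaluate(cA, cB, solution.lam, solution.status)
    return final


def _solution_invariants_ok(tree, clones, cA, cB, run_bound) -> bool:
    profile = CloneCNProfile(
        ("s",), tuple([NORMAL_CLONE] + clones),
        np.concatenate([[1], cA])[None, :], np.concatenate([[1], cB])[None, :],
    )
    return loh_persistence_ok(profile, tree) and alternation_ok(profile, tree, run_bound)


def infer_tumour(
    tree: CloneTree,
    proportions: CloneProportions,
    segments: SegmentTable,
    fractional: FractionalCN,
    eligibility: HomDelEligibility | None = None,
    options: SolverOptions | None = None,
) -> tuple[CloneCNProfile, pd.DataFrame]:
    """Infer the full clone copy-number profile, one independent segment at a time.

    Returns the profile (normal clone included) and a per-segment diagnostics
    table with the selected budget, both objective values, the realised event
    count and the solver status.
    """
    options = options or SolverOptions()
    clones = tree.tumour_clones
    missing = set(clones) - set(proportions.clones)
    if missing:
        raise ValidationError(f"clones without proportions: {sorted(missing)}")
    m = len(fractional.segments)
    n = len(clones)
    cA = np.ones((m, n + 1), dtype=np.int64)
    cB = np.ones((m, n + 1), dtype=np.int64)
    diagnostics = []
    lambda_max = options.lambda_max
    if lambda_max is None:
        lambda_max = 4 * len(tree.edges)

    enum_context = None
    if n <= _TieredModel.ENUM_MAX_CLONES:
        enum_context = _EnumContext(
            tree, proportions.for_clones(clones), options,
            max_budget=_TieredModel.ENUM_MAX_BUDGET,
        )
    for seg_index, segment in enumerate(fractional.segments):
        u, est, lo, hi, eligible = _segment_arrays(
            tree, proportions, fractional, eligibility, seg_index
        )
        model = _TieredModel(tree, u, est, lo, hi, eligible, options, enum_context)
        imp_tol = _material_drop(lo, hi, options)
        selector = _make_selector(options, imp_tol)
        solutions = sweep(
            model.solve,
            lambda_max,
            patience=options.patience,
            improvement_tol=imp_tol,
            score=lambda s: s.objective1 * model.weight + s.objective2,
            selector=selector,
        )
        lam_hat = selector(solutions)
        chosen = next(s for s in solutions if s.lam == lam_hat)
        chosen = _canonicalize_extinct(model, chosen, u, options.run_bound)
        cA[seg_index, 1:] = chosen.cA
        cB[seg_index, 1:] = chosen.cB
        diagnostics.append(
            {
                "segment": segment,
                "lambda_hat": lam_hat,
                "obj1": chosen.objective1,
                "obj2": chosen.objective2,
                "events": chosen.events,
                "c_max": model.c_max,
                "status": chosen.status,
            }
        )

    profile = CloneCNProfile(
        fractional.segments, tuple([NORMAL_CLONE] + clones), cA, cB
    )
    return profile, pd.DataFrame(diagnostics)
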