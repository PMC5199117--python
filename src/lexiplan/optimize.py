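"""2-phase epsilon-constraint (2pec) lexicographic fluence optimization.

Given a wish-list (hard maximum-dose constraints plus prioritized convex
objectives), a dose-influence matrix and a phantom, the optimizer produces a
Pareto-optimal fluence plan:

PHASE 1 — objectives are minimized one priority level at a time. After each
stage the attained value is converted into an epsilon-constraint for all
subsequent stages: at the *goal* value when the goal was attained (leaving
slack for lower priorities — the "or even superseded" reading), otherwise at
``attained * (1 + slack_delta)`` (the small slack avoids ill-conditioning
from constraints active exactly at the previous optimum).

PHASE 2 — each objective is revisited in the same order and minimized fully
under all current constraints; its epsilon-constraint is then tightened to
``min(previous bound, attained * (1 + slack_delta))``.

Equal-priority groups are minimized jointly in phase 1 as the unweighted sum
of goal-normalized members (one convex program); each member is then bounded
individually. Maximum-dose objectives use an auxiliary bound variable over
per-voxel linear inequalities — no smooth max surrogate.

Every stage is a convex program over nonnegative fluence, solved with an
augmented-Lagrangian outer loop around bound-constrained quasi-Newton inner
solves, plus lazy row generation for the per-voxel linear constraints: only
a working set of voxel rows enters the Lagrangian, and after each outer
iteration *all* rows are checked and violators added until the full
constraint set is satisfied to the solver tolerance. The optimizer itself
contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .beams import DoseInfluence, dose_from_fluence
from .phantom import Phantom
from .wishlist import ObjectiveSpec, WishList, validate_against
from . import costs

import os
_DEBUG = bool(os.environ.get('LEXIPLAN_DEBUG'))

__all__ = [
    "FluencePlan",
    "OptimizerSettings",
    "StageRecord",
    "OptimizationTrace",
    "InfeasibleError",
    "SolverError",
    "CoverageError",
    "solve_stage",
    "solve_2pec",
    "ensure_coverage",
]


class InfeasibleError(RuntimeError):
    """The active constraint set admits no feasible fluence."""


class SolverError(RuntimeError):
    """The stage solver failed to converge to a feasible point."""


class CoverageError(RuntimeError):
    """PTV coverage criterion unattainable within the retry budget."""

    def __init__(self, message: str, best_v95: float):
        super().__init__(message)
        self.best_v95 = best_v95


@dataclass(frozen=True)
class OptimizerSettings:
    """Deterministic solver settings.

    slack_delta: relative relaxation applied when converting an attained
    objective value into an epsilon-constraint. solver_tol: relative
    feasibility tolerance used when verifying constraints voxelwise.
    """

    slack_delta: float = 0.03
    solver_tol: float = 1e-5         # relative feasibility tolerance
    ftol: float = 3e-4               # outer-loop objective stability tolerance
    al_rho0: float = 10.0            # initial augmented-Lagrangian penalty
    al_growth: float = 5.0           # penalty growth when feasibility stalls
    al_rho_max: float = 3e6          # penalty cap (beyond this the inner solver
                                     # cannot resolve the ill-conditioning)
    feas_accept: float = 1e-2        # stage acceptance: worst relative
                                     # constraint violation tolerated in a
                                     # returned plan (1% of the limit)
    al_max_outer: int = 16           # multiplier updates per stage
    inner_solver: str = "lbfgs"      # 'lbfgs' (bound-constrained quasi-Newton)
                                     # or 'newton' (projected Newton)
    inner_maxiter: int = 80          # inner iterations per multiplier update
    row_batch: int = 2000            # violated voxel rows added per outer round
    lazy_rows: bool = True           # False: keep every cap row in the Lagrangian
    coverage_retries: int = 3
    coverage_tighten: float = 0.5    # multiplies the LTCP bound on each retry
    coverage_v95: float = 99.5       # % of PTV that must receive >= 95% of D^p

    def __post_init__(self):
        if self.slack_delta < 0:
            raise ValueError("slack_delta must be >= 0")
        if self.solver_tol <= 0:
            raise ValueError("solver_tol must be > 0")


@dataclass
class FluencePlan:
    """Nonnegative beamlet weights for a given influence matrix."""

    weights: np.ndarray
    beam_config_ref: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if np.any(self.weights < -1e-12):
            raise ValueError("fluence weights must be >= 0")
        self.weights = np.maximum(self.weights, 0.0)

    def scaled(self, factor: float) -> "FluencePlan":
        return FluencePlan(self.weights * factor, self.beam_config_ref)


@dataclass(frozen=True)
class StageRecord:
    phase: int
    priority: int
    objective: str            # label, e.g. 'p4:small_bowel:eud'
    attained: float
    bound: float | None
    status: str
    n_iter: int


@dataclass
class OptimizationTrace:
    records: list[StageRecord] = field(default_factory=list)

    def add(self, rec: StageRecord) -> None:
        self.records.append(rec)

    def phase(self, phase: int) -> list[StageRecord]:
        return [r for r in self.records if r.phase == phase]

    def final_bounds(self) -> dict[str, float]:
        """Tightest bound imposed per objective label (later records win)."""
        out: dict[str, float] = {}
        for r in self.records:
            if r.bound is not None:
                out[r.objective] = r.bound if r.objective not in out else min(
                    out[r.objective], r.bound)
        return out


# ---------------------------------------------------------------------------
# internal solve context
# ---------------------------------------------------------------------------

class _LinearMaxSet:
    """Per-voxel linear constraints dose_i <= limit on one structure,
    enforced lazily through a persistent working set of rows."""

    def __init__(self, A_struct: sparse.csr_matrix, limit: float, label: str):
        self.A = A_struct
        self.limit = float(limit)
        self.label = label
        self.active = np.empty(0, dtype=np.int64)

    def violations(self, x: np.ndarray, tol_abs: float) -> np.ndarray:
        d = self.A @ x
        return np.flatnonzero(d > self.limit + tol_abs)

    def seed_active(self, x: np.ndarray, n: int) -> None:
        d = self.A @ x
        top = np.argsort(d)[::-1][:n]
        self.active = np.union1d(self.active, top.astype(np.int64))


class _Context:
    """Precomputed structure row submatrices and persistent constraint state."""

    def __init__(self, influence: DoseInfluence, phantom: Phantom,
                 wishlist: WishList, settings: OptimizerSettings):
        self.influence = influence
        self.phantom = phantom
        self.wishlist = wishlist
        self.settings = settings
        self.n = influence.n_beamlets
        self.Dp = wishlist.prescription_dose

        A = influence.matrix.tocsr()
        lookup = -np.ones(int(np.prod(influence.grid_shape)), dtype=np.int64)
        lookup[influence.voxel_rows] = np.arange(len(influence.voxel_rows))
        self._sub: dict[str, sparse.csr_matrix] = {}
        self._colmean: dict[str, np.ndarray] = {}
        for name, mask in phantom.structures.items():
            rows = lookup[np.flatnonzero(mask.ravel())]
            rows = rows[rows >= 0]
            if rows.size:
                self._sub[name] = A[rows]

        # hard constraints as lazy linear sets
        self.hard: list[_LinearMaxSet] = []
        for c in wishlist.constraints:
            if c.structure not in self._sub:
                continue
            limit = c.limit.resolve(self.Dp)
            self.hard.append(_LinearMaxSet(self._sub[c.structure], limit,
                                           f"constraint:{c.structure}:max"))

        # epsilon-constraints accumulated over stages: label -> (spec, bound, set)
        self.eps: dict[str, tuple[ObjectiveSpec, float, _LinearMaxSet | None]] = {}
        # warm-started multipliers of scalar epsilon-constraints
        self.scalar_mult: dict[str, float] = {}

    def sub(self, structure: str) -> sparse.csr_matrix:
        try:
            return self._sub[structure]
        except KeyError:
            raise KeyError(f"structure {structure!r} has no voxels in the body") from None

    def colmean(self, structure: str) -> np.ndarray:
        if structure not in self._colmean:
            As = self.sub(structure)
            self._colmean[structure] = np.asarray(As.mean(axis=0)).ravel()
        return self._colmean[structure]

    def has_structure(self, structure: str) -> bool:
        return structure in self._sub

    def impose(self, spec: ObjectiveSpec, bound: float) -> None:
        lin = None
        if spec.kind == "max":
            prev = self.eps.get(spec.label)
            if prev is not None and prev[2] is not None:
                lin = prev[2]          # keep working rows and multipliers warm
                lin.limit = float(bound)
            else:
                lin = _LinearMaxSet(self.sub(spec.structure), bound,
                                    f"eps:{spec.label}")
        self.eps[spec.label] = (spec, float(bound), lin)

    def objective_value(self, spec: ObjectiveSpec, x: np.ndarray) -> float:
        d = self.sub(spec.structure) @ x
        if spec.kind == "ltcp":
            return costs.ltcp(d, self.Dp, spec.alpha)
        if spec.kind == "eud":
            return costs.geud(d, spec.k)
        if spec.kind == "mean":
            return float(d.mean())
        return float(d.max())


# ---------------------------------------------------------------------------
# smooth objective/constraint terms
# ---------------------------------------------------------------------------

class _SmoothTerm:
    """f(x) and gradient for ltcp (log space), eud and mean terms."""

    def __init__(self, ctx: _Context, spec: ObjectiveSpec):
        self.spec = spec
        self.A = ctx.sub(spec.structure)
        self.Dp = ctx.Dp
        self.N = self.A.shape[0]
        if spec.kind == "mean":
            self.c = ctx.colmean(spec.structure)
        self._memo: tuple[bytes, float, np.ndarray] | None = None

    def value_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        key = x.tobytes()
        if self._memo is not None and self._memo[0] == key:
            return self._memo[1], self._memo[2]
        v, g = self._value_grad(x)
        self._memo = (key, v, g)
        return v, g

    def _value_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        k = self.spec.kind
        if k == "mean":
            return float(self.c @ x), self.c
        d = self.A @ x
        if k == "ltcp":
            alpha = self.spec.alpha
            w = -alpha * (d - self.Dp)
            m = w.max()
            e = np.exp(w - m)
            se = e.sum()
            f = m + np.log(se) - np.log(self.N)       # log LTCP
            g = self.A.T @ (e / se) * (-alpha)
            return float(f), np.asarray(g).ravel()
        if k == "eud":
            kk = self.spec.k
            mx = d.max()
            if mx <= 0:
                return 0.0, np.zeros(x.shape)
            r = d / mx
            Sm = np.mean(r ** kk)
            g_val = mx * Sm ** (1.0 / kk)
            gd = (r ** (kk - 1.0)) * Sm ** (1.0 / kk - 1.0) / self.N
            return float(g_val), np.asarray(self.A.T @ gd).ravel()
        raise AssertionError(k)

    def raw_value(self, x: np.ndarray) -> float:
        """The reported objective value (LTCP itself, not its log)."""
        v, _ = self.value_grad(x)
        return float(np.exp(v)) if self.spec.kind == "ltcp" else v


# ---------------------------------------------------------------------------
# single stage solve
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# single stage solve: augmented Lagrangian with lazy row generation
# ---------------------------------------------------------------------------


def _hess_rows(spec, d: np.ndarray, Dp: float):
    """Row-space curvature of a smooth structure cost at member doses d.

    Returns (w, r) such that the Hessian of the cost (log-LTCP or power-mean
    EUD) with respect to the member doses is diag(w) - r r^T; None when the
    cost is linear (mean) or degenerate."""
    N = d.size
    if spec.kind == "ltcp":
        a = spec.alpha
        wv = -a * (d - Dp)
        m = wv.max()
        e = np.exp(wv - m)
        p = e / e.sum()
        return a * a * p, a * p
    if spec.kind == "eud":
        k = spec.k
        if k == 1:
            return None
        mx = float(d.max())
        if mx <= 0:
            return None
        dd = np.maximum(d, 1e-9 * mx)
        S = float(np.mean((dd / mx) ** k)) * mx ** k
        w = (k - 1.0) * S ** (1.0 / k - 1.0) * dd ** (k - 2.0) / N
        r = np.sqrt(k - 1.0) * S ** (0.5 * (1.0 / k - 2.0)) * dd ** (k - 1.0) / N
        return w, r
    return None


def _quad_form(A: sparse.csr_matrix, w: np.ndarray) -> np.ndarray:
    """Dense n x n matrix A^T diag(w) A for nonnegative weights w."""
    Aw = A.multiply(np.sqrt(np.maximum(w, 0.0))[:, None]).tocsr()
    return np.asarray((Aw.T @ Aw).todense())


def _solve_stage(ctx: _Context, group: list[ObjectiveSpec], x0: np.ndarray,
                 goal_directed: bool = False,
                 targets: dict[str, float] | None = None,
                 ) -> tuple[np.ndarray, dict[str, float], str, int]:
    """Minimize one objective (or equal-priority group) over nonnegative
    fluence subject to all hard constraints and imposed epsilon-constraints.

    The stage is solved with an augmented-Lagrangian (PHR) outer loop around
    bound-constrained L-BFGS-B inner solves. Per-voxel maximum-dose
    constraints enter the Lagrangian only through a lazily grown working set
    of rows; after every outer iteration *all* rows are checked and
    violators are added, so the returned point is feasible for the full
    constraint set to the solver tolerance. Multipliers of the persistent
    constraint sets are warm-started across stages.

    With ``goal_directed`` (phase 1) the solve terminates early once every
    member objective is at or below its goal (or explicit ``targets``) and
    the full constraint set is satisfied: the imposed epsilon-constraint is
    the goal value in that case, so further minimization cannot change any
    downstream stage.

    Returns (x, attained values per objective label, status, inner iterations).
    """
    st = ctx.settings
    n = ctx.n
    Dp = max(ctx.Dp, 1.0)

    max_members = [o for o in group if o.kind == "max"]
    smooth_members = [o for o in group if o.kind != "max"]
    n_aux = len(max_members)
    nz = n + n_aux

    # epigraph row sets for max-type objectives: dose_i - t <= 0
    aux_sets: list[_LinearMaxSet] = []
    for j, o in enumerate(max_members):
        s = _LinearMaxSet(ctx.sub(o.structure), 0.0, f"obj:{o.label}")
        s.aux = n + j
        aux_sets.append(s)

    terms = [_SmoothTerm(ctx, o) for o in smooth_members]
    goals = {o.label: max(abs(o.resolve_goal(ctx.Dp)), 1e-9) for o in group}
    single = len(group) == 1
    goals_raw = targets or {o.label: o.resolve_goal(ctx.Dp) for o in group}

    def goals_met(x: np.ndarray) -> bool:
        return all(ctx.objective_value(o, x) <= goals_raw[o.label] for o in group)

    _memo = {"key": None, "val": None, "grad": None}
    _mode = {"feas_only": False}

    def fobj(z: np.ndarray) -> tuple[float, np.ndarray]:
        if _mode["feas_only"]:
            return 0.0, np.zeros(nz)
        key = z.tobytes()
        if _memo["key"] == key:
            return _memo["val"], _memo["grad"]
        x = z[:n]
        val = 0.0
        g = np.zeros(nz)
        for t in terms:
            v, gx = t.value_grad(x)
            if single:
                # log-LTCP is minimized directly (same minimizer, stable);
                # Gy-valued objectives are scaled to O(1)
                sc = 1.0 if t.spec.kind == "ltcp" else 1.0 / Dp
                val += v * sc
                g[:n] += sc * gx
            elif t.spec.kind == "ltcp":
                ev = np.exp(v) / goals[t.spec.label]
                val += ev
                g[:n] += ev * gx
            else:
                sc = 1.0 / goals[t.spec.label]
                val += v * sc
                g[:n] += sc * gx
        for j, o in enumerate(max_members):
            sc = (1.0 / Dp) if single else 1.0 / goals[o.label]
            val += z[n + j] * sc
            g[n + j] += sc
        _memo.update(key=key, val=val, grad=g)
        return val, g

    # ----- constraint assembly ---------------------------------------------
    lazy_sets: list[_LinearMaxSet] = list(ctx.hard)
    scalar_cons = []          # objects with .eval(z) -> (c_normalized, grad_nz)

    class _ScalarSmooth:
        def __init__(self, term: _SmoothTerm, spec: ObjectiveSpec, bound: float):
            self.term, self.spec, self.bound = term, spec, bound
            self.label = spec.label
            self.sc = 1.0 if spec.kind == "ltcp" else max(abs(bound), 1.0)
            self.logb = np.log(bound) if spec.kind == "ltcp" else None

        def eval(self, z):
            v, g = self.term.value_grad(z[:n])
            if self.spec.kind == "ltcp":
                c = v - self.logb
            else:
                c = (v - self.bound) / self.sc
            grad = np.zeros(nz)
            grad[:n] = g / self.sc
            return c, grad

    class _ScalarMean:
        def __init__(self, cvec: np.ndarray, bound: float, label: str):
            self.cvec, self.bound, self.label = cvec, bound, label
            self.sc = max(abs(bound), 1.0)
            self.grad = np.zeros(nz)
            self.grad[:n] = cvec / self.sc

        def eval(self, z):
            return (float(self.cvec @ z[:n]) - self.bound) / self.sc, self.grad

    for label, (spec, bound, lin) in ctx.eps.items():
        if spec.kind == "max":
            lazy_sets.append(lin)
        elif spec.kind == "mean":
            scalar_cons.append(_ScalarMean(ctx.colmean(spec.structure), bound, label))
        else:
            scalar_cons.append(_ScalarSmooth(_SmoothTerm(ctx, spec), spec, bound))

    lazy_sets.extend(aux_sets)

    # working sets: either every row (default; robust) or a lazily grown
    # subset pruned/seeded per stage, with multipliers warm-started
    for s in lazy_sets:
        is_aux = getattr(s, "aux", None) is not None
        if not st.lazy_rows:
            if s.active.size != s.A.shape[0]:
                old = s.active
                s.active = np.arange(s.A.shape[0], dtype=np.int64)
                s.mult = _align_mult(old, getattr(s, "mult", np.empty(0)), s.active)
            elif not hasattr(s, "mult") or len(s.mult) != s.active.size:
                s.mult = np.zeros(s.active.size)
            s.sc = max(abs(s.limit), 1.0) if not is_aux else Dp
            s.Aw = s.A
            continue
        if not hasattr(s, "mult") or len(s.mult) != s.active.size:
            s.mult = np.zeros(s.active.size)
        if s.active.size and not is_aux:
            d_act = s.A[s.active] @ x0
            keep = d_act > 0.7 * s.limit
            s.active, s.mult = s.active[keep], s.mult[keep]
        if s.active.size < 30:
            old = s.active
            s.seed_active(x0, min(30, s.A.shape[0]))
            s.mult = _align_mult(old, s.mult, s.active)
        s.sc = max(abs(s.limit), 1.0) if not is_aux else Dp
        s.Aw = s.A[s.active]

    tol_rel = st.solver_tol
    y_scalar = np.array([ctx.scalar_mult.get(c.label, 0.0) for c in scalar_cons])
    rho_holder = {"rho": st.al_rho0, "s_mult": 100.0}

    z = np.empty(nz)
    z[:n] = x0
    for j, o in enumerate(max_members):
        z[n + j] = float((ctx.sub(o.structure) @ x0).max())

    # phase-1 shortcut: nothing to solve if every goal is already met at a
    # point feasible for the full constraint set
    if goal_directed and goals_met(x0):
        if _worst_violation(ctx, lazy_sets, scalar_cons, z, n) <= tol_rel:
            attained = {o.label: ctx.objective_value(o, x0) for o in group}
            return x0.copy(), attained, "goal attained at entry", 0

    # all plain (non-epigraph) working rows are stacked into one sparse
    # matrix so each Lagrangian evaluation is a single matvec pair
    plain_sets = [s for s in lazy_sets if getattr(s, "aux", None) is None]
    pack: dict = {}

    def _repack_mult():
        if pack.get("sets"):
            pack["mult"] = np.concatenate([s.mult for s in pack["sets"]])

    def _repack_rows():
        act = [s for s in plain_sets if s.active.size]
        pack.clear()
        if not act:
            return
        pack["sets"] = act
        W = sparse.vstack([s.Aw for s in act], format="csr")
        pack["W"] = W
        pack["WT"] = W.T.tocsr()
        pack["lim"] = np.concatenate([np.full(s.active.size, s.limit) for s in act])
        pack["sc"] = np.concatenate([np.full(s.active.size, s.sc) for s in act])
        pack["splits"] = np.cumsum([s.active.size for s in act])[:-1]
        _repack_mult()

    _repack_rows()

    def lagrangian(z: np.ndarray) -> tuple[float, np.ndarray]:
        rho = rho_holder["rho"]
        val, g = fobj(z)
        total = float(val)
        grad = g.copy()
        x = z[:n]
        if pack:
            d = pack["W"] @ x
            c = (d - pack["lim"]) / pack["sc"]
            y = np.maximum(0.0, pack["mult"] + rho * c)
            total += float((y - pack["mult"]) @ (y + pack["mult"])) / (2.0 * rho)
            grad[:n] += pack["WT"] @ (y / pack["sc"])
        for s in aux_sets:
            if s.active.size == 0:
                continue
            d = s.Aw @ x
            c = (d - z[s.aux]) / s.sc
            y = np.maximum(0.0, s.mult + rho * c)
            total += float((y - s.mult) @ (y + s.mult)) / (2.0 * rho)
            if (y > 0).any():
                w = y / s.sc
                grad[:n] += s.Aw.T @ w
                grad[s.aux] -= w.sum()
        rho_s = min(rho * rho_holder["s_mult"], 1e9)
        for j, con in enumerate(scalar_cons):
            c, gz = con.eval(z)
            y = max(0.0, y_scalar[j] + rho_s * c)
            total += (y * y - y_scalar[j] ** 2) / (2.0 * rho_s)
            if y > 0:
                grad += y * gz
        return total, grad


    gram = {}

    def _refresh_gram(x_ref: np.ndarray) -> None:
        """Gram matrix of near-active cap rows (within 10% of their limit at
        the reference point); frozen between row-set changes. The Newton
        metric uses it in place of the exact hinge active set — gradients
        stay exact, so this only affects the step quality."""
        gram.clear()
        if pack:
            d = pack["W"] @ x_ref
            c = (d - pack["lim"]) / pack["sc"]
            near = c > -0.1
            if near.any():
                Wn = pack["W"][near].multiply(
                    (1.0 / pack["sc"][near])[:, None]).tocsr()
                gram["K"] = np.asarray((Wn.T @ Wn).todense())
        for s_ in aux_sets:
            if s_.active.size == 0:
                continue
            d = s_.Aw @ x_ref
            t0 = float(d.max())
            near = d > 0.9 * t0
            Wn = s_.Aw[near].tocsr()
            sc2 = 1.0 / (s_.sc * s_.sc)
            gram[("aux", s_.aux)] = (
                sc2 * np.asarray((Wn.T @ Wn).todense()),
                sc2 * np.asarray(Wn.sum(axis=0)).ravel(),
                sc2 * int(near.sum()),
            )

    def _assemble_hessian(z: np.ndarray) -> np.ndarray:
        rho = rho_holder["rho"]
        rho_s = min(rho * rho_holder["s_mult"], 1e9)
        x = z[:n]
        H = np.zeros((nz, nz))

        def add_term_curvature(A, spec, coef):
            d = A @ x
            parts = _hess_rows(spec, d, ctx.Dp)
            if parts is None or coef == 0.0:
                return
            w, r = parts
            H[:n, :n] += coef * _quad_form(A, w)
            u = np.asarray(A.T @ r).ravel()
            H[:n, :n] -= coef * np.outer(u, u)

        for t in ([] if _mode["feas_only"] else terms):
            if single:
                coef = 1.0 if t.spec.kind == "ltcp" else 1.0 / Dp
                add_term_curvature(t.A, t.spec, coef)
            elif t.spec.kind == "ltcp":
                v, gx = t.value_grad(x)
                ev = np.exp(v) / goals[t.spec.label]
                add_term_curvature(t.A, t.spec, ev)
                H[:n, :n] += ev * np.outer(gx, gx)
            else:
                add_term_curvature(t.A, t.spec, 1.0 / goals[t.spec.label])

        if "K" in gram:
            H[:n, :n] += rho * gram["K"]
        for key, val in gram.items():
            if isinstance(key, tuple) and key[0] == "aux":
                Kxx, col, cnt = val
                aux = key[1]
                H[:n, :n] += rho * Kxx
                H[:n, aux] -= rho * col
                H[aux, :n] -= rho * col
                H[aux, aux] += rho * cnt

        for j, con in enumerate(scalar_cons):
            c, gz = con.eval(z)
            y_eff = max(0.0, y_scalar[j] + rho_s * c)
            if y_eff <= 0.0:
                continue
            H += rho_s * np.outer(gz, gz)
            if hasattr(con, "term"):
                add_term_curvature(con.term.A, con.spec, y_eff / con.sc)
        return H

    def _newton_inner(z: np.ndarray, max_it: int):
        """Projected Newton on the augmented Lagrangian over z >= 0."""
        val, g = lagrangian(z)
        H = _assemble_hessian(z)
        ridge = 1e-8 * max(1.0, float(np.trace(H)) / nz)
        done = 0
        small_steps = 0
        cf, free_key = None, None
        for it in range(max_it):
            clamped = (z <= 0.0) & (g > 0.0)
            pg = np.where(clamped, 0.0, g)
            f_scale = 1.0 + abs(fobj(z)[0])
            if np.max(np.abs(pg)) <= 1e-7 * f_scale:
                return z, done, "inner converged"
            free = ~clamped
            k = int(free.sum())
            key = free.tobytes()
            if cf is None or key != free_key:
                Hf = H[np.ix_(free, free)] + ridge * np.eye(k)
                try:
                    cf = cho_factor(Hf, lower=True, check_finite=False)
                except np.linalg.LinAlgError:
                    Hf = Hf + 1e-4 * (np.trace(Hf) / k) * np.eye(k)
                    cf = cho_factor(Hf, lower=True, check_finite=False)
                free_key = key
            p = cho_solve(cf, -g[free], check_finite=False)
            step = np.zeros(nz)
            step[free] = p
            slope = float(g[free] @ p)
            if slope >= 0.0:
                step = -pg
                slope = -float(pg @ pg)
            alpha, ok = 1.0, False
            for _ in range(30):
                z_t = np.maximum(z + alpha * step, 0.0)
                val_t, g_t = lagrangian(z_t)
                if val_t <= val + 1e-4 * alpha * slope + 1e-13 * abs(val):
                    ok = True
                    break
                alpha *= 0.5
            if not ok:
                return z, done, "inner line search stalled"
            z, val, g = z_t, val_t, g_t
            if alpha < 0.25:
                small_steps += 1
                if small_steps >= 2:      # metric went stale; rebuild it
                    _refresh_gram(z[:n])
                    H = _assemble_hessian(z)
                    ridge = 1e-8 * max(1.0, float(np.trace(H)) / nz)
                    cf, free_key = None, None
                    small_steps = 0
            else:
                small_steps = 0
            done += 1
        return z, done, "inner iteration limit"


    def _objective_hessian(z: np.ndarray) -> np.ndarray:
        x = z[:n]
        H = np.zeros((nz, nz))
        for t in terms:
            d = t.A @ x
            parts = _hess_rows(t.spec, d, ctx.Dp)
            v, gx = t.value_grad(x)
            if single:
                coef = 1.0 if t.spec.kind == "ltcp" else 1.0 / Dp
            elif t.spec.kind == "ltcp":
                coef = np.exp(v) / goals[t.spec.label]
                H[:n, :n] += coef * np.outer(gx, gx)
            else:
                coef = 1.0 / goals[t.spec.label]
            if parts is not None:
                w, r = parts
                H[:n, :n] += coef * _quad_form(t.A, w)
                u = np.asarray(t.A.T @ r).ravel()
                H[:n, :n] -= coef * np.outer(u, u)
        return H


    def _solve_equality(z_start, cons_sel, pinned):
        """Newton solve of: minimize f subject to the selected constraints
        as equalities and the pinned variables fixed at zero."""
        z = z_start.copy()
        z[pinned] = 0.0
        free = ~pinned
        k = int(free.sum())
        for _ in range(25):
            val, g = fobj(z)
            H = _objective_hessian(z)[np.ix_(free, free)]
            H[np.diag_indices_from(H)] += 1e-10 * max(1.0, np.trace(H) / max(k, 1))
            rows = [cf(z) for cf in cons_sel]
            m = len(rows)
            if m:
                J = np.stack([gi[free] for _, gi in rows])
                c = np.array([ci for ci, _ in rows])
            else:
                J = np.zeros((0, k))
                c = np.zeros(0)
            K = np.zeros((k + m, k + m))
            K[:k, :k] = H
            K[:k, k:] = J.T
            K[k:, :k] = J
            if m:
                lam, *_ = np.linalg.lstsq(J.T, -g[free], rcond=None)
            else:
                lam = np.zeros(0)
            rhs = np.concatenate([-(g[free] + (J.T @ lam if m else 0.0)), -c])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                return None
            dz = np.zeros(nz)
            dz[free] = sol[:k]
            step = float(np.max(np.abs(dz))) if k else 0.0
            if not np.isfinite(step) or step > 10.0 * (1.0 + float(np.max(np.abs(z)))):
                return None
            z = z + dz
            if step <= 1e-12 * (1.0 + float(np.max(np.abs(z)))):
                break
        if (z < -1e-8).any():
            return None
        return np.maximum(z, 0.0)

    def _enumerate_polish(z0: np.ndarray) -> np.ndarray:
        """Exhaustive active-set refinement for small stage problems: every
        subset of near-active constraints and near-zero variable pins is
        solved as an equality-constrained program; the best feasible result
        wins. Complete for convex problems when the true active set is among
        the candidates."""
        from itertools import combinations

        cand_funs = []
        x0 = z0[:n]
        for s_ in lazy_sets:
            aux = getattr(s_, "aux", None)
            d = s_.A @ x0
            lim = float(z0[aux]) if aux is not None else s_.limit
            for i in range(s_.A.shape[0]):
                row = s_.A[int(i)].toarray().ravel()

                def cf(z, row=row, s_=s_, aux=aux):
                    lim = z[aux] if aux is not None else s_.limit
                    gi = np.zeros(nz)
                    gi[:n] = row / s_.sc
                    if aux is not None:
                        gi[aux] = -1.0 / s_.sc
                    return (float(row @ z[:n]) - lim) / s_.sc, gi

                cand_funs.append(cf)
        for con in scalar_cons:
            cand_funs.append(con.eval)
        if nz <= 6:
            pin_cands = list(range(nz))
        else:
            pin_cands = [int(i) for i in np.flatnonzero(z0 <= 0.05 * max(z0.max(), 1e-9))]
        if len(cand_funs) > 14 or len(pin_cands) > 6 or nz > 8:
            return _kkt_polish(z0)

        def all_feasible(z):
            return _worst_violation(ctx, lazy_sets, scalar_cons, z, n) <= 10 * tol_rel

        best, f_best = z0, fobj(z0)[0]
        idx = range(len(cand_funs))
        for n_pin in range(len(pin_cands) + 1):
            for pins in combinations(pin_cands, n_pin):
                pinned = np.zeros(nz, dtype=bool)
                pinned[list(pins)] = True
                max_cons = int((~pinned).sum())
                for n_act in range(min(len(cand_funs), max_cons) + 1):
                    for sel in combinations(idx, n_act):
                        z = _solve_equality(z0, [cand_funs[j] for j in sel], pinned)
                        if z is None or not all_feasible(z):
                            continue
                        f_z = fobj(z)[0]
                        if f_z < f_best - 1e-14 * (1.0 + abs(f_best)):
                            best, f_best = z, f_z
        return best

    def _kkt_polish(z0: np.ndarray) -> np.ndarray:
        """Newton refinement of the stage KKT system on the active set
        identified by the augmented-Lagrangian phase; the activity threshold
        is swept and a candidate is accepted only if it stays feasible and
        improves the objective."""
        best = z0
        f_best, _ = fobj(z0)
        for tol_act in (1e-3, 1e-4, 1e-5, 50.0 * tol_rel):
            cand = _kkt_polish_at(z0, tol_act)
            f_c, _ = fobj(cand)
            if f_c < f_best:
                best, f_best = cand, f_c
        return best

    def _kkt_polish_at(z0: np.ndarray, tol_act: float) -> np.ndarray:
        z = z0.copy()

        def active_constraints(z):
            cons = []      # (value, grad) with value = 0 at the boundary
            x = z[:n]
            for s_ in lazy_sets:
                aux = getattr(s_, "aux", None)
                lim = z[aux] if aux is not None else s_.limit
                d = s_.A @ x
                rows = np.flatnonzero(d >= lim - tol_act * s_.sc)
                for i in rows:
                    gi = np.zeros(nz)
                    gi[:n] = s_.A[int(i)].toarray().ravel() / s_.sc
                    if aux is not None:
                        gi[aux] = -1.0 / s_.sc
                    cons.append(((d[i] - lim) / s_.sc, gi))
            for j, con in enumerate(scalar_cons):
                c, gz = con.eval(z)
                if c >= -tol_act:
                    cons.append((c, gz))
            return cons

        f0, _ = fobj(z0)
        for _ in range(30):
            val, g = fobj(z)
            cons = active_constraints(z)
            fixed = (z <= 1e-12) & (g > 0)
            free = ~fixed
            k = int(free.sum())
            if not cons:
                break
            J = np.stack([gi[free] for _, gi in cons])
            c = np.array([ci for ci, _ in cons])
            H = _objective_hessian(z)[np.ix_(free, free)]
            H[np.diag_indices_from(H)] += 1e-10 * max(1.0, np.trace(H) / max(k, 1))
            m = len(cons)
            K = np.zeros((k + m, k + m))
            K[:k, :k] = H
            K[:k, k:] = J.T
            K[k:, :k] = J
            # least-squares multipliers for the current gradient
            lam, *_ = np.linalg.lstsq(J.T, -g[free], rcond=None)
            rhs = np.concatenate([-(g[free] + J.T @ lam), -c])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                break
            dz = np.zeros(nz)
            dz[free] = sol[:k]
            step = float(np.max(np.abs(dz)))
            if not np.isfinite(step) or step > 0.05 * (1.0 + float(np.max(np.abs(z)))):
                break
            z = np.maximum(z + dz, 0.0)
            if step <= 1e-13 * (1.0 + float(np.max(np.abs(z)))):
                break
        f1, _ = fobj(z)
        worst = _worst_violation(ctx, lazy_sets, scalar_cons, z, n)
        if f1 <= f0 + 1e-12 * (1.0 + abs(f0)) and worst <= tol_rel * 10:
            return z
        return z0

    status, nit = "", 0
    f_prev = np.inf
    feas_prev = np.inf
    converged = False
    stalled = 0
    gram_age = 99
    for outer in range(st.al_max_outer):
        if st.inner_solver == "newton" and gram_age >= 4:
            _refresh_gram(z[:n])
            gram_age = 0
        gram_age += 1
        if st.inner_solver == "newton":
            z, k_it, status = _newton_inner(z, st.inner_maxiter)
            inner_done = status in ("inner converged", "inner line search stalled")
        else:
            res = minimize(lagrangian, z, jac=True, method="L-BFGS-B",
                           bounds=[(0.0, None)] * nz,
                           options={"maxiter": st.inner_maxiter, "maxcor": 20,
                                    "ftol": 1e-13, "gtol": 1e-9})
            z, k_it, status = np.maximum(res.x, 0.0), int(res.nit), str(res.message)
            inner_done = True
        nit += k_it
        stalled = stalled + 1 if k_it == 0 else 0
        if stalled >= 2:
            break
        x = z[:n]
        rho = rho_holder["rho"]

        # multiplier updates on working rows + full-set row generation
        feas = 0.0
        rows_changed = False
        for s in lazy_sets:
            aux = getattr(s, "aux", None)
            lim = float(z[aux]) if aux is not None else s.limit
            c_act = None
            if s.active.size:
                c_act = ((s.Aw @ x) - lim) / s.sc
                s.mult = np.maximum(0.0, s.mult + rho * c_act)
                # complementary slackness safeguard: clearly inactive rows
                # carry no dual force
                s.mult[c_act < -0.02] = 0.0
            if s.active.size == s.A.shape[0]:
                feas = max(feas, float(c_act.max()) if c_act is not None else 0.0)
                continue
            d_full = s.A @ x
            c_full = (d_full - lim) / s.sc
            worst = float(c_full.max()) if c_full.size else 0.0
            feas = max(feas, worst)
            viol = np.flatnonzero(c_full > tol_rel)
            if viol.size:
                add = _top_rows_from(d_full, viol, st.row_batch)
                old = s.active
                s.active = np.union1d(s.active, add)
                if s.active.size != old.size:
                    s.mult = _align_mult(old, s.mult, s.active)
                    s.Aw = s.A[s.active]
                    rows_changed = rows_changed or aux is None
        if rows_changed:
            _repack_rows()
            gram_age = 99
        else:
            _repack_mult()
        rho_s = min(rho * rho_holder["s_mult"], 1e9)
        for j, con in enumerate(scalar_cons):
            c, _ = con.eval(z)
            y_scalar[j] = max(0.0, y_scalar[j] + rho_s * c)
            if c < -0.02:
                y_scalar[j] = 0.0
            feas = max(feas, c)

        f_now, _ = fobj(z)
        break_tol = max(tol_rel, 0.25 * st.feas_accept)
        if _DEBUG:
            n_act = sum(s.active.size for s in lazy_sets)
            print(f"    outer {outer}: f={f_now:.6f} feas={feas:.2e} "
                  f"rho={rho:.1e} rows={n_act} nit={k_it}", flush=True)
        if feas <= break_tol:
            if goal_directed and goals_met(x):
                status = "goal attained"
                converged = True
                break
            if inner_done and abs(f_now - f_prev) <= st.ftol * max(1.0, abs(f_now)):
                converged = True
                break
            # feasible but the objective still drifts: the scalar duals lag;
            # stiffen only their penalty so the cap hinges stay tractable
            rho_holder["s_mult"] = min(rho_holder["s_mult"] * st.al_growth, 1e7)
        if feas > 0.5 * feas_prev:
            rho_holder["rho"] = min(rho * st.al_growth, st.al_rho_max)
        feas_prev = min(feas_prev, feas)
        f_prev = f_now
    if not converged:
        x = z[:n]
        worst, where = _worst_violation(ctx, lazy_sets, scalar_cons, z, n,
                                        with_label=True)
        if worst > st.feas_accept:
            # feasibility restoration: drop the objective and drive the
            # penalties alone from the current point
            _mode["feas_only"] = True
            _memo["key"] = None
            rho_holder["rho"] = st.al_rho_max
            # pure-penalty feasibility restoration: stale duals would bias
            # the equilibrium toward trading one violation for another
            y_scalar[:] = 0.0
            for s_ in lazy_sets:
                if s_.active.size:
                    s_.mult = np.zeros(s_.active.size)
            for _ in range(6):
                if st.inner_solver == "newton":
                    _refresh_gram(z[:n])
                    z, k_it, _st = _newton_inner(z, st.inner_maxiter)
                else:
                    res = minimize(lagrangian, z, jac=True, method="L-BFGS-B",
                                   bounds=[(0.0, None)] * nz,
                                   options={"maxiter": 2 * st.inner_maxiter,
                                            "maxcor": 20, "ftol": 1e-13,
                                            "gtol": 1e-10})
                    z, k_it = np.maximum(res.x, 0.0), int(res.nit)
                nit += k_it
                for s_ in lazy_sets:
                    if s_.active.size == 0:
                        continue
                    lim = float(z[s_.aux]) if getattr(s_, "aux", None) is not None else s_.limit
                    c_act = ((s_.Aw @ z[:n]) - lim) / s_.sc
                    s_.mult = np.maximum(0.0, s_.mult + rho_holder["rho"] * c_act)
                    s_.mult[c_act < -0.02] = 0.0
                rho_s = min(rho_holder["rho"] * rho_holder["s_mult"], 1e9)
                for j, con in enumerate(scalar_cons):
                    c, _ = con.eval(z)
                    y_scalar[j] = max(0.0, y_scalar[j] + rho_s * c)
                    if c < -0.02:
                        y_scalar[j] = 0.0
                worst, where = _worst_violation(ctx, lazy_sets, scalar_cons, z, n,
                                                with_label=True)
                if worst <= 0.2 * st.feas_accept:
                    break
            _mode["feas_only"] = False
            _memo["key"] = None
        if worst > st.feas_accept:
            raise InfeasibleError(
                f"stage {[o.label for o in group]} ended infeasible "
                f"(relative violation {worst:.2e} on {where}; status: {status})")
        status += " (outer budget reached)"


    if st.inner_solver == "newton" and not (goal_directed and status == "goal attained"):
        z = _enumerate_polish(z)

    x = z[:n]
    for j, con in enumerate(scalar_cons):
        ctx.scalar_mult[con.label] = float(y_scalar[j])
    attained = {o.label: ctx.objective_value(o, x) for o in group}
    return x, attained, status, nit


def _worst_violation(ctx, lazy_sets, scalar_cons, z, n, with_label=False):
    """Worst relative violation over the true constraint set (hard caps and
    epsilon-constraints). Epigraph rows of max-type objectives are excluded:
    a lagging auxiliary bound variable affects only the objective bookkeeping,
    and attained values are recomputed exactly from the dose."""
    x = z[:n]
    worst, where = 0.0, ""
    for s in lazy_sets:
        if getattr(s, "aux", None) is not None:
            continue
        if not hasattr(s, "sc"):
            s.sc = max(abs(s.limit), 1.0)
        d = s.A @ x
        v = float(((d - s.limit) / s.sc).max())
        if v > worst:
            worst, where = v, s.label
    for con in scalar_cons:
        c, _ = con.eval(z)
        if c > worst:
            worst, where = c, con.label
    if with_label:
        return worst, where
    return worst


def _align_mult(old_active: np.ndarray, old_mult: np.ndarray,
                new_active: np.ndarray) -> np.ndarray:
    """Carry multipliers over to a changed active-row index set."""
    mult = np.zeros(new_active.size)
    if old_active.size:
        pos = np.searchsorted(new_active, old_active)
        ok = (pos < new_active.size)
        ok[ok] &= new_active[pos[ok]] == old_active[ok]
        mult[pos[ok]] = old_mult[ok]
    return mult


def _top_rows_from(d, viol, batch):
    if viol.size <= batch:
        return viol.astype(np.int64)
    order = np.argsort(d[viol])[::-1][:batch]
    return viol[order].astype(np.int64)




# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _uniform_fluence(ctx: _Context) -> np.ndarray:
    """Uniform fluence scaled so the mean PTV dose equals the prescription,
    then pulled inside the hard caps."""
    ones = np.ones(ctx.n)
    mpd = float((ctx.sub("ptv") @ ones).mean())
    x0 = ones * (ctx.Dp / mpd) if mpd > 0 else ones
    return _pull_feasible(ctx, x0)


def _pull_feasible(ctx: _Context, x0: np.ndarray) -> np.ndarray:
    worst = 0.0
    for s in ctx.hard:
        d = s.A @ x0
        if d.size:
            worst = max(worst, float(d.max()) / s.limit)
    if worst > 1.0:
        x0 = x0 / (worst * (1.0 + 1e-9))
    return x0


def _initial_fluence(ctx: _Context) -> np.ndarray:
    """Warm start: maximize the minimum PTV dose subject to (sampled) hard
    caps — a linear program solved with HiGHS — then rescale so the full cap
    row sets are satisfied. Falls back to a scaled uniform fluence."""
    from scipy.optimize import linprog

    n = ctx.n
    try:
        Aptv = ctx.sub("ptv")
        step = max(1, Aptv.shape[0] // 2000)
        Ap = Aptv[::step].tocsr()
        rows = [sparse.hstack([-Ap, np.ones((Ap.shape[0], 1))])]
        rhs = [np.zeros(Ap.shape[0])]
        for s in ctx.hard:
            k = max(1, s.A.shape[0] // 4000)
            As = s.A[::k]
            rows.append(sparse.hstack([As, np.zeros((As.shape[0], 1))]))
            rhs.append(np.full(As.shape[0], s.limit))
        A_ub = sparse.vstack(rows).tocsc()
        b_ub = np.concatenate(rhs)
        # maximize the minimum PTV dose, with a mild mean-dose tie-break so
        # the start already carries prescription-level target dose
        c = np.zeros(n + 1)
        c[:n] = -0.5 * np.asarray(Ap.mean(axis=0)).ravel()
        c[-1] = -1.0
        bounds = [(0.0, None)] * n + [(0.0, 1.2 * ctx.Dp)]
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
        if res.status == 0 and res.x is not None:
            return _pull_feasible(ctx, np.maximum(res.x[:n], 0.0))
    except Exception:
        pass
    return _uniform_fluence(ctx)


def solve_stage(influence: DoseInfluence, phantom: Phantom, wishlist: WishList,
                objective: ObjectiveSpec | list[ObjectiveSpec],
                imposed: list[tuple[ObjectiveSpec, float]] = (),
                settings: OptimizerSettings | None = None,
                x0: np.ndarray | None = None,
                ) -> tuple[FluencePlan, dict[str, float], str]:
    """Solve a single epsilon-constraint stage.

    ``wishlist`` supplies the hard constraints and prescription dose;
    ``imposed`` lists (objective, bound) epsilon-constraints from earlier
    stages. Returns the plan, attained value(s) keyed by objective label,
    and the solver status string.
    """
    settings = settings or OptimizerSettings()
    ctx = _Context(influence, phantom, wishlist, settings)
    for spec, bound in imposed:
        ctx.impose(spec, bound)
    group = objective if isinstance(objective, list) else [objective]
    start = x0 if x0 is not None else _initial_fluence(ctx)
    x, attained, status, _ = _solve_stage(ctx, group, np.asarray(start, dtype=float))
    return FluencePlan(x), attained, status


def solve_2pec(influence: DoseInfluence, phantom: Phantom, wishlist: WishList,
               settings: OptimizerSettings | None = None,
               bound_overrides: dict[str, float] | None = None,
               ) -> tuple[FluencePlan, OptimizationTrace]:
    """Run the full 2-phase epsilon-constraint lexicographic optimization.

    ``bound_overrides`` (label -> bound) caps the epsilon-constraint imposed
    for specific objectives; used by :func:`ensure_coverage` to force better
    target coverage on retries.
    """
    settings = settings or OptimizerSettings()
    overrides = bound_overrides or {}
    issues = validate_against(wishlist, phantom)
    errors = [i for i in issues if i.level == "error"]
    if errors:
        raise ValueError("wish-list does not fit phantom: "
                         + "; ".join(i.message for i in errors))
    for c in wishlist.constraints:
        if c.limit.resolve(wishlist.prescription_dose) <= 0:
            raise InfeasibleError(f"hard constraint on {c.structure!r} has limit <= 0")

    ctx = _Context(influence, phantom, wishlist, settings)
    trace = OptimizationTrace()
    x = _initial_fluence(ctx)
    delta = settings.slack_delta

    groups = [
        (prio, [o for o in grp if ctx.has_structure(o.structure)])
        for prio, grp in wishlist.priority_groups()
    ]

    # PHASE 1 ----------------------------------------------------------------
    for prio, grp in groups:
        if not grp:
            continue
        targets = {
            o.label: min(o.resolve_goal(ctx.Dp), overrides.get(o.label, np.inf))
            for o in grp
        }
        x, attained, status, nit = _solve_stage(ctx, grp, x, goal_directed=True,
                                                targets=targets)
        for o in grp:
            a = attained[o.label]
            goal = o.resolve_goal(ctx.Dp)
            bound = goal if a <= goal else a * (1.0 + delta)
            if o.label in overrides:
                bound = min(bound, overrides[o.label])
            ctx.impose(o, bound)
            trace.add(StageRecord(1, prio, o.label, a, bound, status, nit))

    # PHASE 2 ----------------------------------------------------------------
    for prio, grp in groups:
        for o in grp:
            x, attained, status, nit = _solve_stage(ctx, [o], x)
            a = attained[o.label]
            prev = ctx.eps[o.label][1]
            bound = min(prev, a * (1.0 + delta))
            if o.label in overrides:
                bound = min(bound, overrides[o.label])
            ctx.impose(o, bound)
            trace.add(StageRecord(2, prio, o.label, a, bound, status, nit))

    plan = FluencePlan(x, beam_config_ref=f"beams={getattr(influence.config, 'n_beams', '?')}")
    _verify_final(ctx, x)
    return plan, trace


def _verify_final(ctx: _Context, x: np.ndarray) -> None:
    accept = ctx.settings.feas_accept
    for s in ctx.hard:
        d = s.A @ x
        rel = float((d - s.limit).max()) / max(abs(s.limit), 1.0)
        if rel > accept:
            raise SolverError(
                f"final plan violates {s.label} by {rel:.2e} (relative)")
    for label, (spec, bound, _) in ctx.eps.items():
        v = ctx.objective_value(spec, x)
        if (v - bound) / max(abs(bound), 1e-9) > accept:
            raise SolverError(f"final plan violates epsilon bound {label}: {v} > {bound}")


def ensure_coverage(plan: FluencePlan, influence: DoseInfluence, phantom: Phantom,
                    wishlist: WishList, settings: OptimizerSettings | None = None,
                    trace: OptimizationTrace | None = None,
                    ) -> tuple[FluencePlan, OptimizationTrace]:
    """Guarantee the clinical coverage criterion on the normalized plan.

    After normalizing a copy of the plan to median PTV dose = D^p, the PTV
    V_95% must reach the configured threshold (default 99.5%). If not, the
    LTCP epsilon-constraint is tightened by ``coverage_tighten`` and both
    phases are re-run, up to ``coverage_retries`` times. The returned plan is
    *not* normalized (normalization is an evaluation-time step).
    """
    settings = settings or OptimizerSettings()
    ltcp_specs = [o for o in wishlist.objectives if o.kind == "ltcp"]
    if not ltcp_specs:
        raise ValueError("wish-list has no LTCP objective to tighten")
    label = ltcp_specs[0].label
    Dp = wishlist.prescription_dose

    def v95_of(p: FluencePlan) -> float:
        dose = dose_from_fluence(influence, p.weights)
        ptv = dose.values_in(phantom.mask("ptv"))
        med = float(np.median(ptv))
        if med <= 0:
            return 0.0
        d_norm = ptv * (Dp / med)
        return 100.0 * float(np.mean(d_norm >= 0.95 * Dp))

    best_plan, best_trace, best_v95 = plan, trace, v95_of(plan)
    if best_v95 >= settings.coverage_v95:
        return best_plan, (best_trace or OptimizationTrace())

    bound = None
    if trace is not None:
        bound = trace.final_bounds().get(label)
    if bound is None:
        bound = float(ltcp_specs[0].goal)

    for _ in range(settings.coverage_retries):
        bound *= settings.coverage_tighten
        try:
            cand, cand_trace = solve_2pec(influence, phantom, wishlist, settings,
                                          bound_overrides={label: bound})
        except InfeasibleError:
            break
        v = v95_of(cand)
        if v > best_v95:
            best_plan, best_trace, best_v95 = cand, cand_trace, v
        if v >= settings.coverage_v95:
            return cand, cand_trace
    raise CoverageError(
        f"PTV V95 criterion ({settings.coverage_v95}%) unattainable within "
        f"{settings.coverage_retries} retries; best achieved {best_v95:.2f}%",
        best_v95=best_v95,
    )
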