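"""Redundant muscle-force distribution by quadratic optimization.

Six muscles drive two joint axes, so the torque demand underdetermines the
muscle forces. The cascade strategy resolves the redundancy with

    minimise   sum_i (F_i / A_i)^2
    such that  sum_i r_ij F_i = T_j   (j = FE, RUD)
               sum_i F_i = rho
               F_i >= 0

where ``A_i`` is the PCSA of muscle i, ``r_ij`` its moment arm about axis j,
``T_j`` the demanded torque and ``rho`` the muscle impedance — the total
muscle force, the co-contraction handle.

The problem is a tiny strictly convex QP (diagonal Hessian, 3 equalities,
nonnegativity bounds). It is solved here with a primal active-set method on
the bounds with direct KKT solves; an exhaustive active-set enumeration
oracle is provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, nnls

from .muscles import MuscleSet


@dataclass
class TorqueDemand:
    """Demanded joint torques, N m."""

    t_fe: float
    t_rud: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_fe) and np.isfinite(self.t_rud)):
            raise ValueError("torque demand must be finite")


@dataclass
class QPConfig:
    rho: float = 140.0        # N, total-force (impedance) level
    tol: float = 1e-9         # KKT / feasibility tolerance
    max_iter: int = 100
    enforce_f_max: bool = False  # optionally add F_i <= f_max (off by default)

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError("rho must be > 0")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass
class QPSolution:
    forces: np.ndarray            # per-muscle N
    objective: float              # sum (F_i / A_i)^2
    active_set: tuple[int, ...]   # indices clamped at zero
    feasible: bool                # all three equalities met
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _constraints(muscles: MuscleSet, rho: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Equality system A F = b: two torque rows (moment arms mm -> m) and,
    if rho is given, the total-force row."""
    A = (muscles.moment_arms * 1e-3).T  # 2 x n
    if rho is not None:
        A = np.vstack([A, np.ones((1, len(muscles)))])
    return A, A.shape[0]


def _kkt_solve(H: np.ndarray, A: np.ndarray, b: np.ndarray,
               free: np.ndarray,
               fixed_vals: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Solve min 1/2 x'Hx s.t. A x = b with x[i] pinned to fixed_vals[i]
    (zero by default) for i not free, by the direct KKT linear system.
    Returns (x, nu) with nu the equality multipliers."""
    n = H.shape[0]
    nf = int(free.sum())
    m = A.shape[0]
    x = np.zeros(n)
    if fixed_vals is not None:
        x[~free] = fixed_vals[~free]
    Af = A[:, free]
    K = np.zeros((nf + m, nf + m))
    K[:nf, :nf] = np.diag(H[free, free])
    K[:nf, nf:] = Af.T
    K[nf:, :nf] = Af
    rhs = np.concatenate([np.zeros(nf), b - A[:, ~free] @ x[~free]])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    x[free] = sol[:nf]
    nu = sol[nf:]
    return x, nu


def solve_force_distribution(demand: TorqueDemand, muscles: MuscleSet,
                             qp: QPConfig | None = None) -> QPSolution:
    """Solve the muscle-force QP for one torque demand.

    Returns the unique global minimizer when the constraint system admits a
    nonnegative solution. If the total-force level ``rho`` is inconsistent
    with the torque demand, the rho constraint is dropped, the relaxed
    problem (torque equalities only) is solved, and the solution is flagged
    ``feasible=False`` — the torque demand takes priority so a running
    controller is never left without a command.
    """
    if qp is None:
        qp = QPConfig()
    n = len(muscles)
    H = np.diag(2.0 / muscles.pcsa ** 2)
    A_full, _ = _constraints(muscles, qp.rho)
    b_full = np.array([demand.t_fe, demand.t_rud, qp.rho])
    ub = muscles.f_max if qp.enforce_f_max else np.full(n, np.inf)

    x0 = _feasible_point(A_full, b_full, ub)
    if x0 is not None:
        x, at_lo = _active_set(H, A_full, b_full, x0, ub, qp)
        res = A_full @ x - b_full
        return QPSolution(forces=x, objective=float(np.sum((x / muscles.pcsa) ** 2)),
                          active_set=tuple(np.flatnonzero(at_lo)),
                          feasible=bool(np.max(np.abs(res)) <= qp.tol * max(1.0, qp.rho)),
                          residuals=res)

    # rho inconsistent with the demand: relax the total-force constraint
    A_t, _ = _constraints(muscles, None)
    b_t = np.array([demand.t_fe, demand.t_rud])
    x0 = _feasible_point(A_t, b_t, ub)
    if x0 is not None:
        x, at_lo = _active_set(H, A_t, b_t, x0, ub, qp)
    else:
        # torque demand itself unattainable: nonnegative least squares
        x, _ = nnls(A_t, b_t)
        at_lo = x <= qp.tol
    res = A_full @ x - b_full
    return QPSolution(forces=x, objective=float(np.sum((x / muscles.pcsa) ** 2)),
                      active_set=tuple(np.flatnonzero(at_lo)),
                      feasible=False, residuals=res)


def _feasible_point(A: np.ndarray, b: np.ndarray, ub: np.ndarray) -> np.ndarray | None:
    # cheap attempt first: minimum-norm correction of an interior guess —
    # strictly feasible for typical in-band torque demands, skipping the LP
    guess = np.full(A.shape[1], b[-1] / A.shape[1] if A.shape[0] == 3 else 1.0)
    x0 = guess + np.linalg.lstsq(A, b - A @ guess, rcond=None)[0]
    if np.all(x0 >= 0.0) and np.all(x0 <= ub) \
            and np.max(np.abs(A @ x0 - b)) <= 1e-9 * max(1.0, np.abs(b).max()):
        return x0
    res = linprog(np.zeros(A.shape[1]), A_eq=A, b_eq=b,
                  bounds=[(0.0, u if np.isfinite(u) else None) for u in ub],
                  method="highs")
    return res.x if res.status == 0 else None


def _active_set(H: np.ndarray, A: np.ndarray, b: np.ndarray, x0: np.ndarray,
                ub: np.ndarray, qp: QPConfig) -> tuple[np.ndarray, np.ndarray]:
    """Primal active-set iteration on the bound constraints 0 <= x <= ub
    from a primal feasible start. Returns (x, at_lower_bound).
    Deterministic: ties broken by lowest index."""
    x = np.clip(x0, 0.0, ub)
    at_lo = x <= qp.tol
    at_hi = (ub - x) <= qp.tol
    h = np.diag(H).copy()
    bounds = np.where(at_hi, ub, 0.0)
    for _ in range(qp.max_iter):
        work = at_lo | at_hi
        free = ~work
        if free.sum() == 0:
            at_lo[np.argmax(h)] = at_hi[np.argmax(h)] = False
            continue
        bounds = np.where(at_hi, ub, 0.0)
        xeq, nu = _kkt_solve(H, A, b, free, bounds)
        p = xeq - x
        if np.max(np.abs(p)) <= qp.tol:
            # stationary on the working set: check bound multipliers
            grad = h * x + A.T @ nu
            lam = np.where(at_lo, grad, np.where(at_hi, -grad, np.inf))
            worst = int(np.argmin(lam))
            if lam[worst] >= -qp.tol:
                return np.clip(x, 0.0, ub), at_lo
            at_lo[worst] = at_hi[worst] = False
            continue
        # step toward xeq, blocked by the first bound crossed
        alpha, block, block_hi = 1.0, -1, False
        for i in np.flatnonzero(free):
            if p[i] < -qp.tol and x[i] + p[i] < 0.0:
                a = -x[i] / p[i]
                if a < alpha:
                    alpha, block, block_hi = a, i, False
            elif p[i] > qp.tol and x[i] + p[i] > ub[i]:
                a = (ub[i] - x[i]) / p[i]
                if a < alpha:
                    alpha, block, block_hi = a, i, True
        x = x + alpha * p
        if block >= 0:
            if block_hi:
                x[block] = ub[block]
                at_hi[block] = True
            else:
                x[block] = 0.0
                at_lo[block] = True
    return np.clip(x, 0.0, ub), at_lo


def oracle_enumerate(demand: TorqueDemand, muscles: MuscleSet,
                     qp: QPConfig | None = None) -> QPSolution:
    """Exhaustive verification oracle: enumerate all 2^n active sets.

    For each subset of muscles clamped to zero, solves the remaining
    equality-constrained QP through its linear KKT system, keeps candidates
    that are primal feasible (forces >= 0, equalities met) and returns the
    one with the smallest objective. Exponential in n — verification only.
    """
    if qp is None:
        qp = QPConfig()
    n = len(muscles)
    if n > 12:
        raise ValueError("oracle limited to <= 12 muscles")
    H = np.diag(2.0 / muscles.pcsa ** 2)
    A, _ = _constraints(muscles, qp.rho)
    b = np.array([demand.t_fe, demand.t_rud, qp.rho])
    ftol = qp.tol * max(1.0, qp.rho) * 10
    best: QPSolution | None = None
    for mask in range(2 ** n):
        free = np.array([(mask >> i) & 1 == 0 for i in range(n)])
        if free.sum() == 0:
            continue
        x, _ = _kkt_solve(H, A, b, free)
        if np.min(x) < -ftol:
            continue
        if np.max(np.abs(A @ x - b)) > ftol:
            continue
        obj = float(np.sum((x / muscles.pcsa) ** 2))
        if best is None or obj < best.objective - 1e-15:
            best = QPSolution(forces=np.maximum(x, 0.0), objective=obj,
                              active_set=tuple(np.flatnonzero(~free)),
                              feasible=True, residuals=A @ x - b)
    if best is None:
        return QPSolution(forces=np.zeros(n), objective=0.0, active_set=tuple(),
                          feasible=False,
                          residuals=A @ np.zeros(n) - b)
    return best


def feasibility_check(demand: TorqueDemand, muscles: MuscleSet,
                      rho: float) -> dict:
    """Report whether a total-force level rho is achievable for a demand.

    Solves the LP min sum F_i s.t. torque equalities, F >= 0 for the
    minimum total force, and the corresponding maximization under the
    f_max bounds for the maximum. ``rho_feasible`` means
    min_total <= rho <= max_total.
    """
    A, _ = _constraints(muscles, None)
    b = np.array([demand.t_fe, demand.t_rud])
    n = len(muscles)
    lo = linprog(np.ones(n), A_eq=A, b_eq=b, bounds=(0, None), method="highs")
    if lo.status != 0:
        return {"min_total_force": np.inf, "max_total_force": -np.inf,
                "rho_feasible": False,
                "reason": "torque demand unachievable at any force level"}
    hi = linprog(-np.ones(n), A_eq=A, b_eq=b,
                 bounds=[(0, u) for u in muscles.f_max], method="highs")
    max_total = -hi.fun if hi.status == 0 else np.inf
    min_total = float(lo.fun)
    ok = min_total <= rho <= max_total
    out = {"min_total_force": min_total, "max_total_force": float(max_total),
           "rho_feasible": bool(ok)}
    if not ok:
        out["reason"] = ("rho below minimum total force" if rho < min_total
                         else "rho above maximum achievable total force")
    return out


def batch_solve(demands_csv, out_csv, muscles: MuscleSet,
                qp: QPConfig | None = None) -> None:
    """Offline batch mode: CSV of (t_fe, t_rud, rho) rows in, CSV of six
    forces + feasibility out."""
    import pandas as pd

    df = pd.read_csv(demands_csv)
    for col in ("t_fe", "t_rud", "rho"):
        if col not in df.columns:
            raise ValueError(f"demands file missing column {col!r}")
    rows = []
    for _, r in df.iterrows():
        cfg = QPConfig(rho=float(r["rho"]), **({} if qp is None else
                                               {"tol": qp.tol, "max_iter": qp.max_iter}))
        sol = solve_force_distribution(TorqueDemand(float(r["t_fe"]),
                                                    float(r["t_rud"])),
                                       muscles, cfg)
        row = {f"F_{name}": f for name, f in zip(muscles.names, sol.forces)}
        row["feasible"] = sol.feasible
        row["objective"] = sol.objective
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_csv, index=False)
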