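"""Branch continuation, two-parameter phenotype region maps and
loop-knockdown scans.

One-parameter diagrams use pseudo-arclength continuation with fold
(saddle-node) detection by turning points of the continuation
parameter, refined by bisection on the tangent.  Two-parameter maps are
grid-based: every cell runs a warm-started multistart Newton solve and
records which phenotypes are simultaneously stable, which reproduces
the mono-/bi-/tri-/tetra-stable zone structure; fold curves are the
boundaries of those zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import types
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ModelState,
    N_SPECIES,
    SPECIES,
    ParameterError,
    ParameterSet,
    apply_loop_knockdown,
    jacobian,
    rhs,
)
from .steady import (
    SteadyState,
    _dedupe,
    _newton_batch,
    _relax,
    archetype_states,
    classify_phenotype,
)

__all__ = [
    "BranchDiagram",
    "RegionMap",
    "continue_branch",
    "sweep_states",
    "region_map",
    "knockdown_scan",
    "TABLE1_CONDITIONS",
]


# --------------------------------------------------------------------------
# one-parameter continuation
# --------------------------------------------------------------------------

@dataclass
class BranchDiagram:
    """A continued branch of steady states along one parameter."""

    parameter: str
    values: np.ndarray          # (n,) parameter values along the branch
    states: np.ndarray          # (n, 10)
    stable: np.ndarray          # (n,) bool
    folds: list[tuple[float, np.ndarray]] = field(default_factory=list)
    truncated: str | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, self.parameter, self.values)
        df["stable"] = self.stable
        return df


def _extended_jacobian(x, lam, params: ParameterSet, parameter: str):
    """d rhs / d(x, lam) with lam the continuation parameter."""
    lam = max(lam, 0.0)
    p = params.replace(**{parameter: max(lam, 1e-12)})
    Jx = jacobian(x, p)
    h = max(abs(lam), 1e-4) * 1e-6
    lp, lm = lam + h, max(lam - h, 1e-12)
    fp = rhs(x, params.replace(**{parameter: lp}))
    fm = rhs(x, params.replace(**{parameter: lm}))
    Jl = (fp - fm) / (lp - lm)
    return Jx, Jl


def _corrector(x0, lam0, params, parameter, tangent, x_pred, lam_pred,
               max_iter=12, tol=1e-10):
    """Newton on rhs(x; lam)=0 plus the arclength hyperplane condition."""
    xc, lc = x_pred.copy(), lam_pred
    for _ in range(max_iter):
        p = params.replace(**{parameter: max(lc, 1e-12)})
        f = rhs(np.maximum(xc, 0.0), p)
        g = tangent[:N_SPECIES] @ (xc - x_pred) + tangent[N_SPECIES] * (lc - lam_pred)
        if np.abs(f).max() < tol and abs(g) < tol:
            return np.maximum(xc, 0.0), lc, True
        Jx, Jl = _extended_jacobian(np.maximum(xc, 0.0), max(lc, 0.0), params, parameter)
        A = np.zeros((N_SPECIES + 1, N_SPECIES + 1))
        A[:N_SPECIES, :N_SPECIES] = Jx
        A[:N_SPECIES, N_SPECIES] = Jl
        A[N_SPECIES, :] = tangent
        b = np.concatenate([-f, [-g]])
        try:
            d = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return xc, lc, False
        xc = xc + d[:N_SPECIES]
        lc = lc + d[N_SPECIES]
        if not np.all(np.isfinite(xc)) or not np.isfinite(lc):
            return x0, lam0, False
    return np.maximum(xc, 0.0), lc, False


def _tangent(x, lam, params, parameter, previous=None):
    Jx, Jl = _extended_jacobian(x, lam, params, parameter)
    A = np.zeros((N_SPECIES + 1, N_SPECIES + 1))
    A[:N_SPECIES, :N_SPECIES] = Jx
    A[:N_SPECIES, N_SPECIES] = Jl
    A[N_SPECIES, :] = previous if previous is not None else np.eye(N_SPECIES + 1)[-1]
    b = np.zeros(N_SPECIES + 1)
    b[-1] = 1.0
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        t = np.linalg.lstsq(A, b, rcond=None)[0]
    n = np.linalg.norm(t)
    if n == 0:
        raise ParameterError("degenerate tangent in continuation")
    t = t / n
    if previous is not None and t @ previous < 0:
        t = -t
    return t


def continue_branch(
    params: ParameterSet,
    parameter: str,
    p_range: tuple[float, float],
    start_state,
    max_step: float = 0.05,
    min_step: float = 1e-6,
    max_points: int = 4000,
) -> BranchDiagram:
    """Pseudo-arclength continuation of one steady-state branch.

    ``start_state`` must be a steady state at ``p_range[0]``.  Folds are
    recorded where the branch turns in the continuation parameter (sign
    change of the tangent's parameter component), refined by bisection.
    If the adaptive step collapses below ``min_step`` the branch is
    returned truncated with a diagnostic, never silently.
    """
    lo, hi = map(float, p_range)
    x = np.asarray(start_state, dtype=float).copy()
    lam = lo
    p0 = params.replace(**{parameter: max(lam, 1e-12)})
    if np.abs(rhs(x, p0)).max() > 1e-9:
        r = _newton_batch(p0, x[None, :])
        if not len(r):
            raise ParameterError("start_state is not a steady state at the range start")
        x = r[0]

    vals, states, stabs = [lam], [x.copy()], []
    folds: list[tuple[float, np.ndarray]] = []
    truncated = None

    def is_stable(xx, ll):
        J = jacobian(xx, params.replace(**{parameter: max(ll, 1e-12)}))
        return bool(np.linalg.eigvals(J).real.max() < -1e-8)

    stabs.append(is_stable(x, lam))
    t = _tangent(x, lam, params, parameter)
    if t[N_SPECIES] < 0:
        t = -t
    step = max_step / 4
    for _ in range(max_points):
        x_pred = x + step * t[:N_SPECIES]
        lam_pred = lam + step * t[N_SPECIES]
        xn, ln, ok = _corrector(x, lam, params, parameter, t, x_pred, lam_pred)
        if not ok:
            step *= 0.4
            if step < min_step:
                truncated = f"step collapsed below {min_step:g} at {parameter}={lam:.6g}"
                break
            continue
        tn = _tangent(xn, ln, params, parameter, previous=t)
        if tn[N_SPECIES] * t[N_SPECIES] < 0:
            # fold between the two samples: bisect the arclength step
            a_x, a_l, a_t, s = x.copy(), lam, t.copy(), step
            b_l, b_x = ln, xn.copy()
            for _bi in range(40):
                s *= 0.5
                if s < 1e-10:
                    break
                m_x, m_l, ok2 = _corrector(
                    a_x, a_l, params, parameter, a_t,
                    a_x + s * a_t[:N_SPECIES], a_l + s * a_t[N_SPECIES],
                )
                if not ok2:
                    break
                m_t = _tangent(m_x, m_l, params, parameter, previous=a_t)
                if m_t[N_SPECIES] * a_t[N_SPECIES] < 0:
                    b_x, b_l = m_x, m_l
                else:
                    a_x, a_l, a_t = m_x, m_l, m_t
            folds.append((float(b_l), b_x.copy()))
        x, lam, t = xn, ln, tn
        vals.append(lam)
        states.append(x.copy())
        stabs.append(is_stable(x, lam))
        step = min(step * 1.3, max_step)
        if lam > hi + 1e-12 or lam < lo - 1e-12:
            break
        if np.any(x > 1e4):
            truncated = "state exceeded bounds"
            break
    return BranchDiagram(
        parameter=parameter,
        values=np.array(vals),
        states=np.stack(states),
        stable=np.array(stabs, dtype=bool),
        folds=folds,
        truncated=truncated,
    )


# --------------------------------------------------------------------------
# dense sweeps (grid-scan oracle) and region maps
# --------------------------------------------------------------------------

_FIXED_STARTS = np.array([
    [0.05, 0.002, 0.1, 0.4, 3e-4, 0.07, 0.4, 2.0, 2.0, 0.02],    # E-like
    [0.2, 0.012, 3.5, 0.004, 8e-4, 0.09, 0.33, 1.8, 0.5, 0.4],   # I1-like
    [0.3, 0.014, 4.0, 0.002, 0.007, 0.75, 0.31, 0.3, 0.35, 1.7], # I2-like
    [0.8, 0.016, 4.8, 0.001, 0.028, 4.7, 0.011, 0.3, 0.06, 1.8], # M-like
    [1e-3] * N_SPECIES,
])


def _cell_states(params: ParameterSet, warm: np.ndarray, extra: np.ndarray) -> np.ndarray:
    starts = np.vstack([warm, extra]) if len(warm) else extra
    roots = _newton_batch(params, starts, max_iter=40)
    return _dedupe(roots)


def sweep_states(
    params: ParameterSet,
    parameter: str,
    values: Sequence[float],
    n_random: int = 24,
    seed: int = 0,
    relax_first: bool = True,
) -> list[list[SteadyState]]:
    """Steady states along a dense one-parameter grid (warm-started).

    Serves as the independent oracle for fold locations: the count of
    stable states changes by one at each saddle-node crossing.
    """
    rng = np.random.default_rng(seed)
    rand = 10 ** rng.uniform(-4, 1, size=(n_random, N_SPECIES))
    warm = np.empty((0, N_SPECIES))
    out: list[list[SteadyState]] = []
    for v in values:
        p = params.replace(**{parameter: float(v)})
        extra = np.vstack([_FIXED_STARTS, rand])
        if relax_first:
            extra = np.vstack([extra, _relax(p, _FIXED_STARTS, t_end=300.0, dt=0.05)])
        roots = _cell_states(p, warm, extra)
        warm = roots
        sts: list[SteadyState] = []
        if len(roots):
            J = jacobian(roots, p)
            res = np.abs(rhs(roots, p)).max(axis=1)
            for i, r in enumerate(roots):
                emax = float(np.linalg.eigvals(J[i]).real.max())
                sts.append(SteadyState(ModelState.from_array(np.maximum(r, 0)),
                                       emax < -1e-8, emax, residual=float(res[i])))
        out.append(sts)
    return out


@dataclass
class RegionMap:
    """Stable-phenotype sets over a two-parameter grid."""

    axis1: str
    axis2: str
    grid1: np.ndarray
    grid2: np.ndarray
    labels: list[list[frozenset]]        # [i][j] -> phenotype set
    failed: list[tuple[int, int]] = field(default_factory=list)

    def mask(self, phenotype: str) -> np.ndarray:
        m = np.zeros((len(self.grid1), len(self.grid2)), dtype=bool)
        for i in range(len(self.grid1)):
            for j in range(len(self.grid2)):
                m[i, j] = phenotype in self.labels[i][j]
        return m

    def area(self, phenotype: str) -> int:
        return int(self.mask(phenotype).sum())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.grid1):
            for j, b in enumerate(self.grid2):
                rows.append({
                    self.axis1: a,
                    self.axis2: b,
                    "phenotypes": ",".join(sorted(self.labels[i][j])),
                    "n_stable": len(self.labels[i][j]),
                })
        return pd.DataFrame(rows)


class _ParamView(types.SimpleNamespace):
    """Parameter view whose fields may be numpy arrays aligned with a
    state batch; duck-types ParameterSet for rhs/jacobian."""


def _vec_params(base: ParameterSet, overrides: Mapping[str, np.ndarray]) -> "_ParamView":
    d = {f: getattr(base, f) for f in base.__dataclass_fields__}
    d.update(overrides)
    return _ParamView(**d)


def _newton_rows(base: ParameterSet, pvals: Mapping[str, np.ndarray],
                 x0: np.ndarray, max_iter: int = 38,
                 tol: float = 1e-9) -> np.ndarray:
    """Plain regularised Newton on a flat batch of starts with
    per-element parameter values; converged entries drop out of the
    active set.  Returns (converged mask, final states); entries that
    never converged hold garbage."""
    x = np.clip(np.asarray(x0, dtype=float), 0.0, 1e6)
    eye = np.eye(N_SPECIES)
    n = len(x)
    done = np.zeros(n, dtype=bool)
    idx = np.arange(n)
    for it in range(max_iter):
        act = idx[~done]
        if len(act) == 0:
            break
        pa = _vec_params(base, {k: v[act] for k, v in pvals.items()})
        xa = x[act]
        if it == 14:
            # stragglers: pull them into a basin by direct integration
            # before resuming Newton (handles stiff overshoot regions)
            for _r in range(900):
                xa = np.clip(xa + 0.08 * np.nan_to_num(rhs(xa, pa), nan=0.0), 0.0, 1e6)
            x[act] = xa
        f = rhs(xa, pa)
        fn = np.abs(f).max(axis=1)
        newly = fn < tol
        if newly.any():
            done[act[newly]] = True
            keep = ~newly
            act, xa, f, fn = act[keep], xa[keep], f[keep], fn[keep]
            pa = _vec_params(base, {k: v[act] for k, v in pvals.items()})
            if len(act) == 0:
                break
        J = jacobian(xa, pa)
        JtJ = J.transpose(0, 2, 1) @ J
        lam = 1e-11 * (np.trace(JtJ, axis1=1, axis2=2)[:, None, None] + 1e-12)
        b = -(J.transpose(0, 2, 1) @ f[:, :, None])
        try:
            dx = np.linalg.solve(JtJ + lam * eye, b)[:, :, 0]
        except np.linalg.LinAlgError:
            dx = np.stack([np.linalg.lstsq(Ji, -fi, rcond=None)[0]
                           for Ji, fi in zip(J, f)])
        # crude trust region: cap very large steps
        norm = np.linalg.norm(dx, axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            dx = np.where(norm > 50.0, dx * (50.0 / norm), dx)
        dx = np.nan_to_num(dx)
        # backtracking line search on the residual norm
        step = np.ones(len(xa))
        xn = np.clip(xa + dx, 0.0, 1e6)
        improved = np.zeros(len(xa), dtype=bool)
        for _bt in range(5):
            trial = np.clip(xa + step[:, None] * dx, 0.0, 1e6)
            with np.errstate(all="ignore"):
                ftrial = np.abs(rhs(np.nan_to_num(trial, nan=1e6), pa)).max(axis=1)
            better = (ftrial < fn) & ~improved
            xn[better] = trial[better]
            improved |= better
            if improved.all():
                break
            step[~improved] *= 0.5
        stuck = ~improved
        if stuck.any():
            xn[stuck] = np.clip(xa[stuck] + 0.05 * dx[stuck], 0.0, 1e6)
        xa = xn
        bad = ~np.all(np.isfinite(xa), axis=1)
        if bad.any():
            xa[bad] = 1e6
        x[act] = xa
    p_all = _vec_params(base, pvals)
    f = np.abs(rhs(x, p_all)).max(axis=1)
    return (f < tol), x


def region_map(
    params: ParameterSet,
    axis1: tuple[str, Sequence[float]] | None = None,
    axis2: tuple[str, Sequence[float]] | None = None,
    resolution: int = 64,
    seed: int = 0,
    reference: dict[str, np.ndarray] | None = None,
    n_random: int = 4,
    n_sweeps: int = 4,
) -> RegionMap:
    """Map which phenotypes are stable over a two-parameter grid.

    Defaults to external TGF-β in [0, 10] against Ovol2 basal production
    in (0, 4x basal].  An initial row-batched Newton pass from archetype
    starts is followed by global sweeps in which every cell re-solves
    from the roots of its four neighbours, so branches propagate across
    the whole grid; sweeps stop when no cell gains a root.  Stable roots
    are labelled by nearest basal reference archetype; cells where no
    root converges are recorded in ``failed``, never interpolated.
    """
    if resolution < 8:
        raise ParameterError("resolution must be >= 8 per axis")
    if axis1 is None:
        axis1 = ("tgfb_exo", np.linspace(0.0, 10.0, resolution))
    if axis2 is None:
        axis2 = ("ovol2_basal", np.linspace(1e-3, 4.0 * params.ovol2_basal, resolution))
    name1, grid1 = axis1[0], np.asarray(axis1[1], dtype=float)
    name2, grid2 = axis2[0], np.asarray(axis2[1], dtype=float)
    if reference is None:
        reference = archetype_states(params, seed=seed)
    rng = np.random.default_rng(seed)
    rand = 10 ** rng.uniform(-4, 1, size=(n_random, N_SPECIES))
    base_extra = np.vstack([_FIXED_STARTS, np.stack(list(reference.values())), rand])

    n1, n2 = len(grid1), len(grid2)
    roots_grid: list[list[np.ndarray]] = [
        [np.empty((0, N_SPECIES)) for _ in range(n2)] for _ in range(n1)
    ]

    def solve_batch(starts_per_cell):
        """starts_per_cell: list of (i, j, starts array); batched solve,
        merge converged roots into roots_grid; return #cells that gained."""
        X0 = np.vstack([st for _, _, st in starts_per_cell])
        ii = np.concatenate([np.full(len(st), i) for i, _, st in starts_per_cell])
        jj = np.concatenate([np.full(len(st), j) for _, j, st in starts_per_cell])
        pv = {name1: grid1[ii], name2: grid2[jj]}
        ok, X = _newton_rows(params, pv, X0)
        gained = 0
        for i, j, _ in starts_per_cell:
            sel = ok & (ii == i) & (jj == j)
            if not sel.any():
                continue
            before = len(roots_grid[i][j])
            merged = np.vstack([roots_grid[i][j], X[sel]])
            roots_grid[i][j] = _dedupe(merged)
            gained += len(roots_grid[i][j]) > before
        return gained

    # initial pass: archetype starts everywhere, one batch per row
    for i in range(n1):
        solve_batch([(i, j, base_extra) for j in range(n2)])

    # global neighbour-propagation sweeps
    for _ in range(n_sweeps):
        batch = []
        for i in range(n1):
            for j in range(n2):
                nb = [roots_grid[a][b]
                      for a, b in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1))
                      if 0 <= a < n1 and 0 <= b < n2 and len(roots_grid[a][b])]
                if nb:
                    batch.append((i, j, np.vstack(nb)))
        if not batch or solve_batch(batch) == 0:
            break

    # relaxation fallback for cells that still have no root
    failed: list[tuple[int, int]] = []
    for i in range(n1):
        for j in range(n2):
            if len(roots_grid[i][j]) == 0:
                p = params.replace(**{name1: float(grid1[i]), name2: float(grid2[j])})
                relaxed = _relax(p, base_extra, t_end=400.0, dt=0.05)
                roots_grid[i][j] = _cell_states(p, np.empty((0, N_SPECIES)), relaxed)
                if len(roots_grid[i][j]) == 0:
                    failed.append((i, j))

    # batched stability + phenotype labels
    labels: list[list[frozenset]] = [[frozenset() for _ in range(n2)] for _ in range(n1)]
    flat, ii, jj = [], [], []
    for i in range(n1):
        for j in range(n2):
            if len(roots_grid[i][j]):
                flat.append(roots_grid[i][j])
                ii.append(np.full(len(roots_grid[i][j]), i))
                jj.append(np.full(len(roots_grid[i][j]), j))
    if flat:
        X = np.vstack(flat)
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        J = jacobian(X, _vec_params(params, {name1: grid1[ii], name2: grid2[jj]}))
        emax = np.linalg.eigvals(J).real.max(axis=1)
        stable = emax < -1e-8
        for k in np.flatnonzero(stable):
            st = SteadyState(ModelState.from_array(np.maximum(X[k], 0)), True, float(emax[k]))
            lab = classify_phenotype(st, reference)
            if lab == "unclassified":
                continue
            i, j = int(ii[k]), int(jj[k])
            labels[i][j] = labels[i][j] | {lab}
    return RegionMap(name1, name2, grid1, grid2, labels, failed)


# --------------------------------------------------------------------------
# Table-style knockdown scans
# --------------------------------------------------------------------------

#: printed partial/complete loop-blockage conditions: name ->
#: list of (loop, {symbol: fraction}); percentages are fractions of the
#: basal value of the scaled quantity
TABLE1_CONDITIONS: dict[str, list[tuple[str, dict[str, float]]]] = {
    "mir34:0.1%_1/J2_200": [("mir34_snail", {"1/J2_200": 0.001})],
    "mir34:25%_K_SR_25%_1/J1_34": [("mir34_snail", {"K_SR": 0.25, "1/J1_34": 0.25})],
    "mir34:50%_K_SR_50%_1/J1_34": [("mir34_snail", {"K_SR": 0.5, "1/J1_34": 0.5})],
    "mir34:0.1%_K_SR": [("mir34_snail", {"K_SR": 0.001})],
    "mir200:90%_1/J2_200": [("mir200_zeb", {"1/J2_200": 0.9})],
    "mir200:75%_1/J2_200": [("mir200_zeb", {"1/J2_200": 0.75})],
    "mir200:50%_K_1": [("mir200_zeb", {"K_1": 0.5})],
    "mir200:25%_K_1_25%_1/J2_200": [("mir200_zeb", {"K_1": 0.25, "1/J2_200": 0.25})],
    "both_mirna:complete": [
        ("mir34_snail", {"K_SR": 0.001, "1/J1_34": 0.001}),
        ("mir200_zeb", {"K_1": 0.001, "1/J2_200": 0.001}),
    ],
    "ovol2_zeb:50%_1/J_O": [("ovol2_zeb", {"1/J_O": 0.5})],
    "ovol2_zeb:50%_1/J2_zeb": [("ovol2_zeb", {"1/J2_zeb": 0.5})],
    "ovol2_zeb:25%_1/J_O_25%_1/J2_zeb": [("ovol2_zeb", {"1/J_O": 0.25, "1/J2_zeb": 0.25})],
    "ovol2_zeb:complete": [("ovol2_zeb", {"1/J_O": 0.001, "1/J2_zeb": 0.001})],
}


def _apply_condition(params: ParameterSet, condition) -> ParameterSet:
    p = params
    for loop, scaling in condition:
        p = apply_loop_knockdown(p, loop, scaling)
    return p


def _verdict(area: int, basal_area: int, threshold: float = 0.2) -> str:
    if area == 0:
        return "disappearance"
    if basal_area == 0:
        return "appearance"
    rel = (area - basal_area) / basal_area
    if rel <= -threshold:
        return "decrease"
    if rel >= threshold:
        return "increase"
    return "unchanged"


def _merged(rm: RegionMap, basal: RegionMap) -> bool:
    """I1/I2 merge heuristic: cells that basally carried both
    intermediates now carry exactly one, while the union of the
    intermediate regions keeps at least half its basal area."""
    m1, m2 = rm.mask("I1"), rm.mask("I2")
    b1, b2 = basal.mask("I1"), basal.mask("I2")
    both_basal = b1 & b2
    if not both_basal.any():
        return False
    single_now = both_basal & (m1 ^ m2)
    union_keep = (m1 | m2).sum() >= 0.5 * (b1 | b2).sum()
    return bool(single_now.sum() >= 0.5 * both_basal.sum() and union_keep)


def knockdown_scan(
    params: ParameterSet,
    conditions: Mapping[str, list] | None = None,
    resolution: int = 64,
    seed: int = 0,
    axis1: tuple[str, Sequence[float]] | None = None,
    axis2: tuple[str, Sequence[float]] | None = None,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Per-condition intermediate-region report over the 2-parameter map.

    For each knockdown condition the I1 and I2 region areas (grid-cell
    counts) are compared with the basal map and summarised with the
    qualitative verdicts {disappearance, decrease, increase, unchanged}
    plus a merge flag (declared ±20% area thresholds).
    """
    if conditions is None:
        conditions = TABLE1_CONDITIONS
    reference = archetype_states(params, seed=seed)
    basal = region_map(params, axis1=axis1, axis2=axis2, resolution=resolution,
                       seed=seed, reference=reference)
    rows = []
    base_I1, base_I2 = basal.area("I1"), basal.area("I2")
    rows.append({"condition": "basal", "area_I1": base_I1, "area_I2": base_I2,
                 "verdict_I1": "unchanged", "verdict_I2": "unchanged",
                 "merged": False})
    for name, cond in conditions.items():
        p = _apply_condition(params, cond)
        rm = region_map(p, axis1=axis1, axis2=axis2, resolution=resolution,
                        seed=seed, reference=reference)
        a1, a2 = rm.area("I1"), rm.area("I2")
        rows.append({
            "condition": name,
            "area_I1": a1,
            "area_I2": a2,
            "verdict_I1": _verdict(a1, base_I1, threshold),
            "verdict_I2": _verdict(a2, base_I2, threshold),
            "merged": _merged(rm, basal),
        })
    return pd.DataFrame(rows)
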