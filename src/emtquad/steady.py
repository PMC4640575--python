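"""Steady-state enumeration, linear stability and phenotype labels.

Roots of the vector field are located by multistart damped Newton
iteration (vectorised across starts) seeded from log-uniformly sampled
states plus the endpoints of long relaxation integrations; duplicates
are merged in log-space; stability comes from the eigenvalues of the
finite-difference Jacobian.  Phenotypes are labelled E / I1 / I2 / M by
the E-cadherin ordering convention when four states coexist and by
nearest-neighbour matching against basal reference states otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import (
    IDX,
    N_SPECIES,
    IntegrationError,
    ModelState,
    ParameterError,
    ParameterSet,
    jacobian,
    rhs,
)

__all__ = [
    "SteadyState",
    "NoSteadyStateError",
    "find_steady_states",
    "classify_phenotype",
    "classify_phenotypes",
    "archetype_states",
]

PHENOTYPES = ("E", "I1", "I2", "M")

#: largest real eigenvalue below -STABILITY_MARGIN counts as stable (1/hr)
STABILITY_MARGIN = 1e-8
#: relative log-space distance below which two roots are merged
MERGE_TOL = 1e-4
#: residual tolerance on the infinity norm of the vector field (μM/hr)
RESIDUAL_TOL = 1e-9
#: floor used when mapping concentrations to log space
LOG_FLOOR = 1e-6


class NoSteadyStateError(RuntimeError):
    """The multistart search returned no converged root at all."""


@dataclass(frozen=True)
class SteadyState:
    state: ModelState
    stable: bool
    eigen_max_real: float
    phenotype: str = "unclassified"
    residual: float = 0.0

    @property
    def array(self) -> np.ndarray:
        return self.state.to_array()


# --------------------------------------------------------------------------
# batched numerics
# --------------------------------------------------------------------------

def _relax(params: ParameterSet, x, t_end: float = 400.0, dt: float = 0.02) -> np.ndarray:
    """Cheap batched forward-Euler relaxation toward attractors."""
    x = np.array(x, dtype=float)
    n_steps = int(t_end / dt)
    for _ in range(n_steps):
        x += dt * rhs(x, params)
        np.maximum(x, 0.0, out=x)
        if not np.all(np.isfinite(x)):
            raise IntegrationError("relaxation diverged")
    return x


def _newton_batch(
    params: ParameterSet,
    x0: np.ndarray,
    max_iter: int = 60,
    tol: float = RESIDUAL_TOL,
) -> np.ndarray:
    """Damped (backtracking) Newton on a batch of starts; returns the
    subset of converged roots (possibly empty)."""
    x = np.maximum(np.array(x0, dtype=float), 0.0)
    active = np.ones(len(x), dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        xa = x[active]
        f = rhs(xa, params)
        fn = np.abs(f).max(axis=1)
        done = fn < tol
        if done.all():
            idx = np.flatnonzero(active)
            active[idx[done]] = False
            continue
        J = jacobian(xa, params)
        # Tikhonov-regularised solve keeps near-singular (fold) points tame
        JtJ = J.transpose(0, 2, 1) @ J
        lam = 1e-12 * np.trace(JtJ, axis1=1, axis2=2)[:, None, None]
        rhs_vec = -(J.transpose(0, 2, 1) @ f[:, :, None])
        try:
            dx = np.linalg.solve(JtJ + lam * np.eye(N_SPECIES), rhs_vec)[:, :, 0]
        except np.linalg.LinAlgError:
            dx = np.stack(
                [np.linalg.lstsq(Ji, -fi, rcond=None)[0] for Ji, fi in zip(J, f)]
            )
        # backtracking line search on the residual norm
        step = np.ones(len(xa))
        xn = xa.copy()
        improved = np.zeros(len(xa), dtype=bool)
        for _bt in range(8):
            trial = np.maximum(xa + step[:, None] * dx, 0.0)
            ftrial = np.abs(rhs(trial, params)).max(axis=1)
            better = (ftrial < fn) & ~improved
            xn[better] = trial[better]
            improved |= better
            step[~improved] *= 0.5
            if improved.all():
                break
        # starts that cannot improve keep a tiny step (may still converge)
        stuck = ~improved
        if stuck.any():
            xn[stuck] = np.maximum(xa[stuck] + 0.05 * dx[stuck], 0.0)
        xa_new = x[active]
        xa_new[:] = xn
        x[active] = xa_new
    f = np.abs(rhs(x, params)).max(axis=1)
    return x[f < tol]


def _dedupe(roots: np.ndarray, tol: float = 5e-3) -> np.ndarray:
    """Merge roots closer than ``tol`` in max-abs log10 distance
    (5e-3 decades ~ 1% relative concentration difference)."""
    if len(roots) == 0:
        return roots
    logr = np.log10(np.maximum(roots, LOG_FLOOR))
    kept: list[int] = []
    for i in range(len(roots)):
        if not any(np.max(np.abs(logr[i] - logr[j])) < tol for j in kept):
            kept.append(i)
    return roots[kept]


def _sample_starts(n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = np.log10(1e-4), np.log10(10.0)
    return 10 ** rng.uniform(lo, hi, size=(n, N_SPECIES))


def find_steady_states(
    params: ParameterSet,
    n_starts: int = 500,
    seed: int = 0,
    extra_starts: np.ndarray | None = None,
    relax_fraction: float = 0.2,
) -> list[SteadyState]:
    """Enumerate steady states at fixed parameters.

    Multistart damped-Newton root finding from ``n_starts`` log-uniform
    initial states over [1e-4, 10] μM, augmented with the endpoints of
    long relaxation integrations from a subset of starts (which also
    guarantees every attractor reachable at this sampling density is
    represented).  ``extra_starts`` allows warm-starting from known
    roots, e.g. along a parameter sweep.

    Returns states sorted by descending E-cadherin.  Raises
    :class:`NoSteadyStateError` when no root converges.
    """
    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    starts = _sample_starts(n_starts, rng)
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([np.atleast_2d(extra_starts), starts])
    n_relax = max(4, int(relax_fraction * len(starts)))
    relaxed = _relax(params, starts[:: max(1, len(starts) // n_relax)])
    candidates = np.vstack([starts, relaxed])
    roots = _newton_batch(params, candidates)
    roots = _dedupe(roots)
    if len(roots) == 0:
        raise NoSteadyStateError(
            "no steady state found: all Newton starts failed to converge"
        )
    out: list[SteadyState] = []
    J = jacobian(roots, params)
    res = np.abs(rhs(roots, params)).max(axis=1)
    for i, r in enumerate(roots):
        eig = np.linalg.eigvals(J[i])
        emax = float(eig.real.max())
        out.append(
            SteadyState(
                state=ModelState.from_array(np.maximum(r, 0.0)),
                stable=emax < -STABILITY_MARGIN,
                eigen_max_real=emax,
                residual=float(res[i]),
            )
        )
    out.sort(key=lambda s: -s.state.ECAD)
    return out


# --------------------------------------------------------------------------
# phenotype labels
# --------------------------------------------------------------------------

def _log(x: np.ndarray) -> np.ndarray:
    return np.log10(np.maximum(x, LOG_FLOOR))


_READOUT = (IDX["ECAD"], IDX["VIM"])


def _readout_log(x: np.ndarray) -> np.ndarray:
    """log10 (Ecad, Vim) coordinates: the operational phenotype space
    matching flow-cytometry readouts, used for nearest-archetype
    matching."""
    return np.log10(np.maximum(np.asarray(x)[..., list(_READOUT)], LOG_FLOOR))


def archetype_states(
    params: ParameterSet,
    tgfb_exo: float = 0.5,
    n_starts: int = 400,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Reference E/I1/I2/M states from a basal-parameter condition that
    admits all four phenotypes (the tetra-stable window)."""
    ss = find_steady_states(params.replace(tgfb_exo=tgfb_exo), n_starts=n_starts, seed=seed)
    stable = [s for s in ss if s.stable]
    if len(stable) != 4:
        raise NoSteadyStateError(
            f"reference condition tgfb_exo={tgfb_exo} has {len(stable)} stable "
            "states; need exactly 4 to define E/I1/I2/M archetypes"
        )
    stable.sort(key=lambda s: -s.state.ECAD)
    return {lab: s.array for lab, s in zip(PHENOTYPES, stable)}


def classify_phenotypes(
    states: list[SteadyState],
    reference: dict[str, np.ndarray] | None = None,
) -> list[SteadyState]:
    """Label the coexisting stable states (unstable ones keep
    ``unclassified``).

    With exactly four stable states, ordering by descending E-cadherin
    gives E, I1, I2, M directly.  Otherwise each stable state is
    matched to the nearest basal reference archetype in log-state
    space, with a one-to-one assignment so no label repeats.  Ties in
    the E-cadherin ordering (beyond a 1e-6 μM resolution) are returned
    as ``unclassified``.
    """
    stable_idx = [i for i, s in enumerate(states) if s.stable]
    labelled = list(states)
    if not stable_idx:
        return labelled
    ecads = np.array([states[i].state.ECAD for i in stable_idx])
    order = np.argsort(-ecads)
    if len(stable_idx) == 4 and reference is None:
        if np.any(np.abs(np.diff(np.sort(ecads))) < 1e-6):
            return labelled  # degenerate tie: leave unclassified
        for lab, pos in zip(PHENOTYPES, order):
            i = stable_idx[pos]
            labelled[i] = replace(states[i], phenotype=lab)
        return labelled
    if reference is None:
        raise ParameterError(
            "reference archetypes are required when fewer (or more) than "
            "4 stable states coexist"
        )
    from scipy.optimize import linear_sum_assignment

    labs = list(reference)
    ref = _readout_log(np.stack([reference[lab] for lab in labs]))
    pts = _readout_log(np.stack([states[i].array for i in stable_idx]))
    full = _log(np.stack([states[i].array for i in stable_idx]))
    # duplicate states (degenerate input) -> unclassified
    for a in range(len(full)):
        for b in range(a + 1, len(full)):
            if np.max(np.abs(full[a] - full[b])) < 1e-6:
                return labelled
    cost = np.linalg.norm(pts[:, None, :] - ref[None, :, :], axis=2)
    if len(stable_idx) <= len(labs):
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            i = stable_idx[r]
            labelled[i] = replace(states[i], phenotype=labs[c])
    else:
        # more stable states than labels: label the best match per label
        rows, cols = linear_sum_assignment(cost.T)
        for lab_i, st_i in zip(rows, cols):
            i = stable_idx[st_i]
            labelled[i] = replace(states[i], phenotype=labs[lab_i])
    return labelled


#: maximum (log Ecad, log Vim) distance, in decades, at which a state
#: may inherit an archetype's label; beyond it the state is unclassified.
#: Sized to cover the drift of each basal branch across its whole
#: stability region (the M branch strays ~0.5 decades at extreme
#: TGF-β), while the hybrid states created by loop ablation sit a full
#: decade or more away and drop out.
CLASSIFY_RADIUS = 0.6


def classify_phenotype(
    ss: SteadyState,
    reference: dict[str, np.ndarray],
    radius: float | None = CLASSIFY_RADIUS,
) -> str:
    """Label a single stable state by its nearest reference archetype.

    Returns ``unclassified`` for unstable states and for states farther
    than ``radius`` (in log Ecad/Vim space) from every archetype;
    ``radius=None`` disables the cutoff.
    """
    if not ss.stable:
        return "unclassified"
    labs = list(reference)
    ref = _readout_log(np.stack([reference[lab] for lab in labs]))
    d = np.linalg.norm(_readout_log(ss.array)[None, :] - ref, axis=1)
    k = int(np.argmin(d))
    if radius is not None and d[k] > radius:
        return "unclassified"
    return labs[k]
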