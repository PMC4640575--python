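"""Stochastic population simulation and basin-of-attraction analysis.

Cells are integrated with Euler–Maruyama under multiplicative white
noise, ``dX = f(X) dt + σ X ∘ dW``, applied by default to the mRNA and
protein species (not the miRNAs).  Non-negativity is enforced by
reflection at zero.  After the noise-off time the ensemble relaxes
deterministically until the vector field is quiescent, and every cell
is assigned to the basin of the nearest stable steady state; cells
that fail to converge are counted, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from .model import (
    IDX,
    N_SPECIES,
    SPECIES,
    IntegrationError,
    ParameterError,
    ParameterSet,
    rhs,
)
from .steady import (
    LOG_FLOOR,
    SteadyState,
    archetype_states,
    classify_phenotype,
    find_steady_states,
)

__all__ = [
    "SimProtocol",
    "PopulationSnapshot",
    "simulate_population",
    "basin_fractions",
    "propensity_vs_parameter",
    "DEFAULT_NOISY_SPECIES",
    "SIGMA_SMALL",
    "SIGMA_LARGE",
]

#: multiplicative noise is applied to mRNA/protein species, not miRNAs
DEFAULT_NOISY_SPECIES = (
    "tgfb_endo", "snail_mrna", "SNAIL", "zeb_mrna", "ZEB", "OVOL2", "ECAD", "VIM",
)

#: calibrated default amplitudes for the "small" / "large fluctuation"
#: protocols (dimensionless multiplicative σ)
SIGMA_SMALL = 0.02
SIGMA_LARGE = 0.30


@dataclass(frozen=True)
class SimProtocol:
    """Ensemble protocol: initial phenotype, noise, horizon, events.

    ``events`` are parameter-change events ``(time_hr, symbol, value)``
    applied in order; an event at t=0 emulates a constitutive
    perturbation (e.g. raising ``ovol2_basal`` to 2 μM/hr) while the
    initial condition is still resolved under the unperturbed
    parameters.
    """

    initial_phenotype: str = "I1"
    sigma: float = SIGMA_LARGE
    dt: float = 0.01
    t_noise_off: float = 300.0
    t_end: float = 400.0
    n_cells: int = 2000
    seed: int = 0
    noisy_species: tuple[str, ...] = DEFAULT_NOISY_SPECIES
    events: tuple[tuple[float, str, float], ...] = ()
    max_extension: float = 2000.0
    convergence_tol: float = 1e-6

    def __post_init__(self):
        if not (0 < self.dt <= 0.1):
            raise ParameterError("dt must be in (0, 0.1] hr")
        if self.t_noise_off > self.t_end:
            raise ParameterError("t_noise_off must be <= t_end")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        unknown = set(self.noisy_species) - set(SPECIES)
        if unknown:
            raise ParameterError(f"unknown noisy species: {sorted(unknown)}")


@dataclass
class PopulationSnapshot:
    """Final per-cell states with basin labels."""

    states: np.ndarray                  # (n_cells, 10)
    basins: np.ndarray                  # (n_cells,) str labels
    converged: np.ndarray               # (n_cells,) bool
    protocol: SimProtocol
    params: ParameterSet
    stable_states: list[SteadyState] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "cell_id", np.arange(len(self.states)))
        df["basin"] = self.basins
        df["converged"] = self.converged
        return df


def _resolve_initial(params: ParameterSet, protocol: SimProtocol,
                     reference: dict[str, np.ndarray] | None):
    """Initial state: the stable steady state carrying the requested
    phenotype label under the *unperturbed* parameters."""
    if reference is None:
        reference = archetype_states(params if params.tgfb_exo > 0
                                     else params.replace(tgfb_exo=0.5),
                                     seed=protocol.seed)
    states = find_steady_states(params, n_starts=120, seed=protocol.seed)
    for s in states:
        if s.stable and classify_phenotype(s, reference) == protocol.initial_phenotype:
            return s.array, reference
    raise ParameterError(
        f"initial phenotype {protocol.initial_phenotype!r} is not a stable "
        "state under the given parameters"
    )


def _euler_maruyama(
    params: ParameterSet,
    x0: np.ndarray,
    protocol: SimProtocol,
    record_every: int | None = None,
    record_index: int | None = None,
):
    """Core ensemble integrator.  Returns (final states, params after all
    events, recorded samples or None).

    One counter-based Philox stream keyed by the protocol seed drives
    the whole ensemble, so a snapshot is bit-reproducible for a given
    (seed, n_cells, dt) regardless of hardware.
    """
    rng = np.random.Generator(np.random.Philox(key=protocol.seed))
    n = protocol.n_cells
    x = np.tile(np.asarray(x0, dtype=float), (n, 1))
    dt = protocol.dt
    sqdt = np.sqrt(dt)
    noisy = np.array([IDX[s] for s in protocol.noisy_species], dtype=int)
    n_steps = int(round(protocol.t_end / dt))
    noise_off_step = int(round(protocol.t_noise_off / dt))
    events = sorted(protocol.events)
    ev_idx = 0
    p = params
    rec: list[np.ndarray] = []
    for k in range(n_steps):
        t = k * dt
        while ev_idx < len(events) and events[ev_idx][0] <= t:
            _, sym, val = events[ev_idx]
            p = p.replace(**{sym: val})
            ev_idx += 1
        f = rhs(x, p, t=t)
        x = x + dt * f
        if protocol.sigma > 0 and k < noise_off_step:
            dW = rng.standard_normal((n, len(noisy)))
            x[:, noisy] += protocol.sigma * x[:, noisy] * sqdt * dW
        np.abs(x, out=x)  # reflecting boundary at 0
        if not np.all(np.isfinite(x)):
            raise IntegrationError("ensemble diverged", t)
        if record_every and k % record_every == 0:
            rec.append(x[:, record_index].copy())
    while ev_idx < len(events):
        _, sym, val = events[ev_idx]
        p = p.replace(**{sym: val})
        ev_idx += 1
    return x, p, (np.array(rec) if record_every else None)


def simulate_population(
    params: ParameterSet,
    protocol: SimProtocol,
    reference: dict[str, np.ndarray] | None = None,
) -> PopulationSnapshot:
    """Simulate an ensemble of cells and label their final basins.

    The initial condition is the steady state with the protocol's
    phenotype label under ``params`` (checked); parameter events are
    then applied during integration.  After ``t_noise_off`` the noise is
    zeroed and the ensemble relaxes; relaxation is extended in blocks
    until ``max |f|`` falls below the convergence tolerance, up to the
    protocol's ``max_extension``.  Unconverged cells are labelled
    ``"unconverged"``.
    """
    x0, reference = _resolve_initial(params, protocol, reference)
    x, p_final, _ = _euler_maruyama(params, x0, protocol)

    # noise-free extension to quiescence (coarser step is safe and fast)
    dt = 0.05
    block = int(100.0 / dt)
    t_extra = 0.0
    resid = np.abs(rhs(x, p_final)).max(axis=1)
    while resid.max() > protocol.convergence_tol and t_extra < protocol.max_extension:
        for _ in range(block):
            x = np.maximum(x + dt * rhs(x, p_final), 0.0)
        t_extra += block * dt
        resid = np.abs(rhs(x, p_final)).max(axis=1)
    converged = resid <= protocol.convergence_tol

    stable = [s for s in find_steady_states(
        p_final, n_starts=100, seed=protocol.seed,
        extra_starts=np.unique(np.round(x, 6), axis=0)[:50],
    ) if s.stable]
    labels = [classify_phenotype(s, reference) for s in stable]
    attract = np.stack([s.array for s in stable])
    la = np.log10(np.maximum(attract, LOG_FLOOR))
    lx = np.log10(np.maximum(x, LOG_FLOOR))
    nearest = np.argmin(
        np.linalg.norm(lx[:, None, :] - la[None, :, :], axis=2), axis=1
    )
    basins = np.array([labels[i] for i in nearest], dtype=object)
    basins[~converged] = "unconverged"
    stable_labeled = [
        SteadyState(s.state, s.stable, s.eigen_max_real, phenotype=lab,
                    residual=s.residual)
        for s, lab in zip(stable, labels)
    ]
    return PopulationSnapshot(
        states=x, basins=basins, converged=converged,
        protocol=protocol, params=p_final, stable_states=stable_labeled,
    )


def basin_fractions(snapshot: PopulationSnapshot) -> pd.DataFrame:
    """Basin occupancy fractions with binomial standard errors."""
    n = len(snapshot.basins)
    rows = []
    for lab in ("E", "I1", "I2", "M", "unconverged"):
        k = int((snapshot.basins == lab).sum())
        f = k / n
        rows.append({"basin": lab, "count": k, "fraction": f,
                     "se": np.sqrt(f * (1 - f) / n)})
    return pd.DataFrame(rows)


def propensity_vs_parameter(
    params: ParameterSet,
    protocol: SimProtocol,
    symbol: str,
    values,
    reference: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Basin fractions as a function of one perturbed parameter.

    Each value is applied as a t=0 parameter event on top of the
    protocol (the initial state stays the unperturbed steady state),
    with a common base seed so runs are paired.
    """
    frames = []
    for v in values:
        if v <= 0:
            raise ParameterError(f"{symbol} must stay positive, got {v}")
        events = ((0.0, symbol, float(v)),) + tuple(
            e for e in protocol.events if e[1] != symbol
        )
        proto_v = _dc_replace(protocol, events=events)
        snap = simulate_population(params, proto_v, reference=reference)
        bf = basin_fractions(snap)
        bf.insert(0, symbol, float(v))
        frames.append(bf)
    return pd.concat(frames, ignore_index=True)
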