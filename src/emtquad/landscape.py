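"""Quasi-potential landscapes from long stochastic runs.

The quasi-potential along a reaction coordinate is estimated as
``U = -ln ρ`` where ρ is the stationary occupancy density pooled over
a noisy ensemble after burn-in.  Minima of U correspond to attractors;
barrier heights order transition difficulty.  The construction is a
projection diagnostic, not a true Freidlin–Wentzell potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IDX, ParameterError, ParameterSet
from .steady import find_steady_states
from .stochastic import SimProtocol, _euler_maruyama, _resolve_initial

__all__ = ["LandscapeProfile", "estimate_landscape", "profile_from_samples"]


@dataclass
class LandscapeProfile:
    coordinate: str
    bin_centers: np.ndarray
    potential: np.ndarray       # U = -ln density, min shifted to 0; NaN where empty
    counts: np.ndarray
    n_samples: int
    basins_visited: int

    def minima(self, prominence: float = 0.5) -> np.ndarray:
        """Coordinate values of the local minima of U.

        Only wells at least ``prominence`` (in units of -ln density,
        i.e. nats) deeper than the lowest surrounding barrier are
        reported; shallower dips are counting noise at typical sample
        sizes.  Edge bins can qualify.
        """
        from scipy.signal import find_peaks

        U = self.potential
        hi = np.nanmax(U) + 2 * prominence + 1.0
        U_f = np.where(np.isfinite(U), U, hi)
        padded = np.concatenate([[-hi], -U_f, [-hi]])
        peaks, _ = find_peaks(padded, prominence=prominence)
        return self.bin_centers[peaks - 1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.coordinate: self.bin_centers,
            "potential": self.potential,
            "count": self.counts,
        })


def estimate_landscape(
    params: ParameterSet,
    protocol: SimProtocol,
    coordinate: str = "ECAD",
    bins: int = 60,
    burn_in_frac: float = 0.2,
    record_every: int = 20,
    log_coordinate: bool = True,
    reference=None,
) -> LandscapeProfile:
    """Estimate the quasi-potential along one coordinate.

    Samples the coordinate every ``record_every`` steps across all
    cells of a noisy run (σ > 0 required; the protocol's noise-off time
    is ignored — noise stays on for the whole horizon), discards the
    first ``burn_in_frac`` of samples, histograms the remainder and
    returns ``U = -ln density`` shifted to min 0.  Empty bins are NaN
    (undefined), not zero.  A post-hoc check counts how many stable
    steady states fall inside the sampled coordinate range; fewer than
    3 emits a warning in the returned profile's ``basins_visited``.
    """
    if protocol.sigma <= 0:
        raise ParameterError("landscape estimation requires sigma > 0")
    if coordinate not in IDX:
        raise ParameterError(f"unknown coordinate {coordinate!r}")
    proto = SimProtocol(
        initial_phenotype=protocol.initial_phenotype,
        sigma=protocol.sigma,
        dt=protocol.dt,
        t_noise_off=protocol.t_end,   # noise on throughout
        t_end=protocol.t_end,
        n_cells=protocol.n_cells,
        seed=protocol.seed,
        noisy_species=protocol.noisy_species,
        events=protocol.events,
    )
    x0, reference = _resolve_initial(params, proto, reference)
    _, p_final, rec = _euler_maruyama(
        params, x0, proto, record_every=record_every, record_index=IDX[coordinate]
    )
    if rec is None or rec.size == 0:
        raise ParameterError("no samples recorded; increase t_end")
    n_burn = int(burn_in_frac * len(rec))
    samples = rec[n_burn:].ravel()
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ParameterError("empty histogram: no finite samples after burn-in")
    centers, U, counts = profile_from_samples(samples, bins=bins,
                                              log_coordinate=log_coordinate)

    stable = [s for s in find_steady_states(p_final, n_starts=150, seed=proto.seed)
              if s.stable]
    lo, hi = samples.min(), samples.max()
    visited = sum(lo <= s.array[IDX[coordinate]] <= hi for s in stable)
    if visited < 3:
        import warnings
        warnings.warn(
            f"landscape sampled only {visited} basins along {coordinate}; "
            "consider a longer horizon or larger sigma",
            stacklevel=2,
        )
    return LandscapeProfile(
        coordinate=coordinate,
        bin_centers=centers,
        potential=U,
        counts=counts,
        n_samples=int(samples.size),
        basins_visited=int(visited),
    )

def profile_from_samples(samples, bins: int = 60, log_coordinate: bool = True):
    """Histogram samples of a coordinate into a quasi-potential.

    Returns ``(bin_centers, U, counts)`` with ``U = -ln density``
    shifted so its minimum is exactly zero; empty bins are NaN.
    """
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ParameterError("empty histogram: no finite samples")
    vals = np.log10(np.maximum(samples, 1e-6)) if log_coordinate else samples
    counts, edges = np.histogram(vals, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if log_coordinate:
        centers = 10.0 ** centers
    with np.errstate(divide="ignore"):
        U = -np.log(counts / counts.sum())
    U[counts == 0] = np.nan
    U = U - np.nanmin(U)
    return centers, U, counts
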