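"""Synthetic flow-cytometry readout stage.

Converts simulated populations into FACS-style Ecad/Vim event tables:
``signal = gain * concentration * LogNormal(0, cv)`` independently per
event and channel.  Also generates reference archetype populations
(E-, I1- and M-like) so that classification pipelines can be exercised
without any measured data.  No spillover/compensation or gating of
real FCS files is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IDX, ParameterError, ParameterSet
from .steady import archetype_states, classify_phenotype, find_steady_states
from .stochastic import PopulationSnapshot

__all__ = ["FlowTable", "to_flow_readout", "generate_reference_archetypes"]

_ECAD, _VIM = IDX["ECAD"], IDX["VIM"]


@dataclass
class FlowTable:
    """Per-event Ecad/Vim fluorescence signals (arbitrary units)."""

    data: pd.DataFrame          # columns: ecad_signal, vim_signal, population
    gain: float
    cv: float
    seed: int

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    # cv == 0 is the noise-free limit
    if cv == 0:
        return np.ones(size)
    return rng.lognormal(mean=0.0, sigma=cv, size=size)


def to_flow_readout(
    snapshot: PopulationSnapshot,
    gain: float = 1000.0,
    cv: float = 0.3,
    seed: int = 0,
) -> FlowTable:
    """FACS-style event table from a simulated population.

    Each cell yields one event per channel with log-normal multiplicative
    measurement noise of coefficient ``cv`` around ``gain * concentration``.
    """
    if gain <= 0:
        raise ParameterError("gain must be > 0")
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    if len(snapshot.states) == 0:
        raise ParameterError("empty snapshot")
    rng = np.random.default_rng(seed)
    ecad = snapshot.states[:, _ECAD]
    vim = snapshot.states[:, _VIM]
    data = pd.DataFrame({
        "ecad_signal": gain * ecad * _lognormal_noise(rng, cv, len(ecad)),
        "vim_signal": gain * vim * _lognormal_noise(rng, cv, len(vim)),
        "population": snapshot.basins,
    })
    return FlowTable(data=data, gain=gain, cv=cv, seed=seed)


def generate_reference_archetypes(
    params: ParameterSet,
    seed: int = 0,
    n_events: int = 2000,
    gain: float = 1000.0,
    cv: float = 0.3,
    tgfb_exo: float = 0.0,
) -> FlowTable:
    """Synthetic E / I1 / M archetype populations at zero TGF-β.

    Samples flow events around the model's E, I1 and M steady states;
    the I1 centroid lies between the E and M centroids in
    (log Ecad, log Vim) space, mirroring the geometry of untreated
    epithelial, intermediate and mesenchymal lines.  Raises an error
    naming any required stable state that is missing.
    """
    reference = archetype_states(params, seed=seed)
    p = params.replace(tgfb_exo=tgfb_exo)
    stable = [s for s in find_steady_states(p, n_starts=200, seed=seed) if s.stable]
    by_label = {classify_phenotype(s, reference): s for s in stable}
    missing = [lab for lab in ("E", "I1", "M") if lab not in by_label]
    if missing:
        raise ParameterError(
            f"required stable state(s) missing at tgfb_exo={tgfb_exo}: {missing}"
        )
    rng = np.random.default_rng(seed)
    frames = []
    for lab in ("E", "I1", "M"):
        x = by_label[lab].array
        frames.append(pd.DataFrame({
            "ecad_signal": gain * x[_ECAD] * _lognormal_noise(rng, cv, n_events),
            "vim_signal": gain * x[_VIM] * _lognormal_noise(rng, cv, n_events),
            "population": lab,
        }))
    return FlowTable(data=pd.concat(frames, ignore_index=True),
                     gain=gain, cv=cv, seed=seed)


def nearest_centroid_labels(table: FlowTable, centroids: dict[str, tuple[float, float]]):
    """Classify events by nearest centroid in (log ecad, log vim) space."""
    pts = np.log10(np.maximum(
        table.data[["ecad_signal", "vim_signal"]].to_numpy(), 1e-12))
    labs = list(centroids)
    cen = np.log10(np.maximum(np.array([centroids[k] for k in labs]), 1e-12))
    d = np.linalg.norm(pts[:, None, :] - cen[None, :, :], axis=2)
    return np.array(labs, dtype=object)[np.argmin(d, axis=1)]
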