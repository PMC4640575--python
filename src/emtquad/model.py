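"""Core dynamical system of the four-state EMT regulatory circuit.

The network couples three mutual-inhibition loops — SNAIL1/miR-34a,
ZEB1/miR-200 and Ovol2/Zeb1 — downstream of a TGF-β input, with
E-cadherin and vimentin as readout species.  Transcription-factor
regulation uses Hill kinetics; miRNA silencing of target mRNAs uses a
binding-site occupancy model in which translation and mRNA degradation
rates depend on the number of miRNA-bound sites.

Concentrations are in μM, time in hours; the exogenous TGF-β input is a
dimensionless signal.  The right-hand side is vectorised: state arrays
of shape ``(..., 10)`` are evaluated in a single call, which the
steady-state and stochastic modules rely on for batched Newton solves
and ensemble integration.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "ParameterError",
    "IntegrationError",
    "ModelState",
    "ParameterSet",
    "hill_repression",
    "hill_activation",
    "mirna_occupancy",
    "effective_rates",
    "rhs",
    "jacobian",
    "apply_loop_knockdown",
    "influence_edges",
    "count_mutual_inhibition_loops",
    "KNOCKDOWN_SYMBOLS",
    "LOOPS",
]

#: Canonical species order used by every array-valued interface (CSV
#: columns, state vectors, Jacobians).
SPECIES = (
    "tgfb_endo",
    "snail_mrna",
    "SNAIL",
    "mir34",
    "zeb_mrna",
    "ZEB",
    "mir200",
    "OVOL2",
    "ECAD",
    "VIM",
)

IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)


class ParameterError(ValueError):
    """A parameter or argument violates its validity constraints."""


class IntegrationError(RuntimeError):
    """Numerical integration produced a non-finite state."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message if t is None else f"{message} (t={t:g} hr)")
        self.t = t


@dataclass(frozen=True)
class ModelState:
    """Concentrations of all dynamic species (μM)."""

    tgfb_endo: float
    snail_mrna: float
    SNAIL: float
    mir34: float
    zeb_mrna: float
    ZEB: float
    mir200: float
    OVOL2: float
    ECAD: float
    VIM: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ModelState":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_SPECIES,):
            raise ValueError(f"expected shape ({N_SPECIES},), got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite concentration in state")
        if np.any(x < 0):
            raise ValueError("negative concentration in state")
        return cls(**{s: float(v) for s, v in zip(SPECIES, x)})


# --------------------------------------------------------------------------
# Elementary kinetic building blocks
# --------------------------------------------------------------------------

def _check_hill(J, n) -> None:
    if np.any(np.asarray(J) <= 0):
        raise ParameterError(f"Hill half-saturation J must be > 0, got {J}")
    if np.any(np.asarray(n) < 1):
        raise ParameterError(f"Hill coefficient n must be >= 1, got {n}")


def hill_repression(x, J, n):
    """Repressive Hill factor ``1 / (1 + (x/J)^n)`` in [0, 1]."""
    _check_hill(J, n)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("Hill input concentration must be >= 0")
    return 1.0 / (1.0 + (x / J) ** n)


def hill_activation(x, J, n):
    """Activating Hill factor ``(x/J)^n / (1 + (x/J)^n)``; complements
    :func:`hill_repression` so the two always sum to one."""
    _check_hill(J, n)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("Hill input concentration must be >= 0")
    u = (x / J) ** n
    return u / (1.0 + u)


def mirna_occupancy(mu, n_sites: int, mu0):
    """Probability weights over the number of miRNA-occupied sites.

    For a target mRNA with ``n_sites`` equivalent binding sites and a
    characteristic miRNA concentration ``mu0``, the weight of the state
    with ``i`` occupied sites is the binomial term
    ``C(n, i) (mu/mu0)^i / (1 + mu/mu0)^n``; the weights sum to one.

    Returns an array whose last axis has length ``n_sites + 1``.
    """
    if int(n_sites) != n_sites or n_sites < 1:
        raise ParameterError(f"n_sites must be an integer >= 1, got {n_sites}")
    if np.any(np.asarray(mu0) <= 0):
        raise ParameterError("mu0 must be > 0")
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ParameterError("miRNA concentration must be >= 0")
    n_sites = int(n_sites)
    u = mu / mu0
    q = u / (1.0 + u)          # per-site occupancy probability
    r = 1.0 / (1.0 + u)
    out = np.empty(np.shape(q) + (n_sites + 1,), dtype=float)
    for i in range(n_sites + 1):
        out[..., i] = math.comb(n_sites, i) * q**i * r ** (n_sites - i)
    return out


def _check_coeffs(coeff_translation, coeff_degradation, n_sites: int) -> None:
    lt = np.asarray(coeff_translation, dtype=float)
    ld = np.asarray(coeff_degradation, dtype=float)
    if lt.shape != (n_sites + 1,) or ld.shape != (n_sites + 1,):
        raise ParameterError(
            f"occupancy coefficient vectors must have length n_sites+1={n_sites + 1}"
        )
    if np.any(lt < 0) or np.any(ld < 0):
        raise ParameterError("occupancy coefficients must be >= 0")
    if np.any(np.diff(lt) > 1e-12):
        raise ParameterError("translation coefficients must be non-increasing")
    if np.any(np.diff(ld) < -1e-12):
        raise ParameterError("degradation coefficients must be non-decreasing")


def effective_rates(
    mrna,
    mu,
    n_sites: int,
    mu0,
    coeff_translation,
    coeff_degradation,
    strength: float = 1.0,
):
    """Occupancy-weighted translation and mRNA-degradation fluxes.

    ``strength`` scales the effective miRNA concentration entering the
    occupancy weights (``mu_eff = strength * mu``); it is the knob the
    loop-knockdown machinery turns for the K_SR / K_1 symbols, with
    ``strength -> 0`` abolishing the silencing arm.

    Returns ``(translation_flux, degradation_flux)``, each equal to
    ``mrna * sum_i coeff[i] * w_i(mu_eff)``.
    """
    _check_coeffs(coeff_translation, coeff_degradation, n_sites)
    if strength < 0:
        raise ParameterError("strength must be >= 0")
    w = mirna_occupancy(np.asarray(mu, dtype=float) * strength, n_sites, mu0)
    lt = np.asarray(coeff_translation, dtype=float)
    ld = np.asarray(coeff_degradation, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    return mrna * (w @ lt), mrna * (w @ ld)


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

_POSITIVE = "strictly positive"

# (field, kind) — kind in {"rate", "conc", "hill_J", "hill_n", "frac", "signal"}
_SCALAR_FIELDS: tuple[tuple[str, str], ...] = (
    ("tgfb_exo", "signal"),
    # endogenous TGF-β
    ("k_T", "rate"), ("J_T200", "hill_J"), ("n_T200", "hill_n"), ("kd_T", "rate"),
    # snail1 mRNA
    ("k0_sm", "rate0"), ("k_sm", "rate"),
    ("J_st", "hill_J"), ("n_st", "hill_n"),
    ("J_OT", "hill_J"), ("n_OT", "hill_n"),
    ("J_ss", "hill_J"), ("n_ss", "hill_n"),
    ("kd_sm", "rate"),
    # SNAIL protein
    ("k_S", "rate"), ("kd_S", "rate"),
    # miR-34a
    ("k0_34", "rate0"), ("k_34", "rate"),
    ("J1_34", "hill_J"), ("n1_34", "hill_n"),
    ("J2_34", "hill_J"), ("n2_34", "hill_n"),
    ("kd_34", "rate"),
    ("mu0_34", "hill_J"), ("K_SR", "rate"),
    # zeb1 mRNA
    ("k0_zm", "rate0"), ("k_zm", "rate"),
    ("J_zs", "hill_J"), ("n_zs", "hill_n"),
    ("J_O", "hill_J"), ("n_O", "hill_n"),
    ("kd_zm", "rate"),
    # ZEB protein
    ("k_Z", "rate"), ("kd_Z", "rate"),
    # miR-200
    ("k0_200", "rate0"), ("k_200", "rate"),
    ("J1_200", "hill_J"), ("n1_200", "hill_n"),
    ("J2_200", "hill_J"), ("n2_200", "hill_n"),
    ("kd_200", "rate"),
    ("mu0_200", "hill_J"), ("K_1", "rate"),
    # OVOL2
    ("ovol2_basal", "rate"), ("leak_O", "frac"),
    ("J2_zeb", "hill_J"), ("n_zeb", "hill_n"),
    ("kd_O", "rate"),
    # E-cadherin readout
    ("k0_E", "rate0"), ("k_E", "rate"),
    ("J_es", "hill_J"), ("n_es", "hill_n"),
    ("J_ez", "hill_J"), ("n_ez", "hill_n"),
    ("kd_E", "rate"),
    # Vimentin readout
    ("k0_V", "rate0"), ("k_V", "rate"),
    ("J_vs", "hill_J"), ("n_vs", "hill_n"),
    ("J_vz", "hill_J"), ("n_vz", "hill_n"),
    ("J_vo", "hill_J"), ("n_vo", "hill_n"),
    ("kd_V", "rate"),
)

_VECTOR_FIELDS = ("l_34", "gamma_34", "l_200", "gamma_200")

PARAM_SYMBOLS = tuple(f for f, _ in _SCALAR_FIELDS) + _VECTOR_FIELDS

#: alias used by figure-style protocols: the zeb1 mRNA basal production rate
ZEB_MRNA_BASAL = "k0_zm"


@dataclass(frozen=True)
class ParameterSet:
    """Complete kinetic parameterisation of the circuit.

    Production rates are μM/hr, degradation rates 1/hr, Hill constants
    μM (except those gauged against the dimensionless TGF-β signal).
    ``l_34``/``l_200`` and ``gamma_34``/``gamma_200`` are the
    occupancy-dependent translation and mRNA-degradation coefficient
    vectors of length ``n_sites + 1``; ``K_SR`` and ``K_1`` are the
    dimensionless silencing strengths of miR-34a on snail1 and miR-200
    on zeb1.
    """

    tgfb_exo: float
    k_T: float
    J_T200: float
    n_T200: float
    kd_T: float
    k0_sm: float
    k_sm: float
    J_st: float
    n_st: float
    J_OT: float
    n_OT: float
    J_ss: float
    n_ss: float
    kd_sm: float
    k_S: float
    kd_S: float
    k0_34: float
    k_34: float
    J1_34: float
    n1_34: float
    J2_34: float
    n2_34: float
    kd_34: float
    mu0_34: float
    K_SR: float
    k0_zm: float
    k_zm: float
    J_zs: float
    n_zs: float
    J_O: float
    n_O: float
    kd_zm: float
    k_Z: float
    kd_Z: float
    k0_200: float
    k_200: float
    J1_200: float
    n1_200: float
    J2_200: float
    n2_200: float
    kd_200: float
    mu0_200: float
    K_1: float
    ovol2_basal: float
    leak_O: float
    J2_zeb: float
    n_zeb: float
    kd_O: float
    k0_E: float
    k_E: float
    J_es: float
    n_es: float
    J_ez: float
    n_ez: float
    kd_E: float
    k0_V: float
    k_V: float
    J_vs: float
    n_vs: float
    J_vz: float
    n_vz: float
    J_vo: float
    n_vo: float
    kd_V: float
    l_34: tuple[float, ...]
    gamma_34: tuple[float, ...]
    l_200: tuple[float, ...]
    gamma_200: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "l_34", tuple(float(v) for v in self.l_34))
        object.__setattr__(self, "gamma_34", tuple(float(v) for v in self.gamma_34))
        object.__setattr__(self, "l_200", tuple(float(v) for v in self.l_200))
        object.__setattr__(self, "gamma_200", tuple(float(v) for v in self.gamma_200))
        self.validate()

    # -- validation --------------------------------------------------------

    @property
    def n_sites_34(self) -> int:
        return len(self.l_34) - 1

    @property
    def n_sites_200(self) -> int:
        return len(self.l_200) - 1

    def validate(self) -> None:
        problems: list[str] = []
        for field, kind in _SCALAR_FIELDS:
            v = getattr(self, field)
            if not np.isfinite(v):
                problems.append(f"{field} is not finite")
                continue
            if kind in ("rate", "hill_J") and v <= 0:
                problems.append(f"{field} must be {_POSITIVE} (got {v})")
            elif kind == "hill_n" and v < 1:
                problems.append(f"{field} must be >= 1 (got {v})")
            elif kind == "rate0" and v < 0:
                problems.append(f"{field} must be >= 0 (got {v})")
            elif kind == "frac" and not (0 <= v < 1):
                problems.append(f"{field} must be in [0, 1) (got {v})")
            elif kind == "signal" and v < 0:
                problems.append(f"{field} must be >= 0 (got {v})")
        for lname, gname in (("l_34", "gamma_34"), ("l_200", "gamma_200")):
            lt, ld = getattr(self, lname), getattr(self, gname)
            if len(lt) != len(ld):
                problems.append(f"{lname} and {gname} must have equal length")
                continue
            if len(lt) < 2:
                problems.append(f"{lname} implies n_sites < 1")
                continue
            try:
                _check_coeffs(lt, ld, len(lt) - 1)
            except ParameterError as exc:
                problems.append(f"{lname}/{gname}: {exc}")
        if problems:
            raise ParameterError("; ".join(problems))

    # -- convenience -------------------------------------------------------

    def replace(self, **changes) -> "ParameterSet":
        unknown = set(changes) - set(PARAM_SYMBOLS)
        if unknown:
            raise ParameterError(f"unknown parameter symbol(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f, _ in _SCALAR_FIELDS}
        for f in _VECTOR_FIELDS:
            d[f] = list(getattr(self, f))
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        missing = [s for s in PARAM_SYMBOLS if s not in d]
        extra = [k for k in d if k not in PARAM_SYMBOLS]
        if missing or extra:
            raise ParameterError(
                f"parameter file mismatch: missing {missing or 'none'}, "
                f"unexpected {extra or 'none'}"
            )
        kwargs = {f: float(d[f]) for f, _ in _SCALAR_FIELDS}
        kwargs.update({f: tuple(d[f]) for f in _VECTOR_FIELDS})
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# --------------------------------------------------------------------------
# Right-hand side
# --------------------------------------------------------------------------

def _hr(x, J, n):
    # unchecked fast path (inputs already validated / clipped at >= 0)
    return 1.0 / (1.0 + (x / J) ** n)


def _silencing(mu, strength, mu0, lt, ld):
    u = mu * (strength / mu0)
    q = u / (1.0 + u)
    r = 1.0 / (1.0 + u)
    n = len(lt) - 1
    L = np.zeros_like(q)
    D = np.zeros_like(q)
    for i in range(n + 1):
        w = math.comb(n, i) * q**i * r ** (n - i)
        L += lt[i] * w
        D += ld[i] * w
    return L, D


def rhs(x, params: ParameterSet, t: float | None = None) -> np.ndarray:
    """Time derivatives (μM/hr) of the circuit; broadcasts over ``(..., 10)``.

    Raises :class:`IntegrationError` when the state contains NaN/Inf.
    """
    p = params
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise IntegrationError("non-finite state passed to rhs", t)
    Tb, sm, S, m34, zm, Z, m200, O, E, V = (x[..., i] for i in range(N_SPECIES))

    T = p.tgfb_exo + Tb

    L34, D34 = _silencing(m34, p.K_SR, p.mu0_34, p.l_34, p.gamma_34)
    L200, D200 = _silencing(m200, p.K_1, p.mu0_200, p.l_200, p.gamma_200)

    u_st = (T / p.J_st) ** p.n_st
    act_T = u_st / (1.0 + u_st)
    u_zs = (S / p.J_zs) ** p.n_zs
    act_S = u_zs / (1.0 + u_zs)

    d = np.empty_like(x)
    # endogenous TGF-β, repressed by miR-200
    d[..., 0] = p.k_T * _hr(m200, p.J_T200, p.n_T200) - p.kd_T * Tb
    # snail1 mRNA: basal plus TGF-activated transcription, gated by OVOL2
    # (attenuation of TGF-β signalling) and SNAIL self-inhibition; miR-34a
    # accelerates mRNA turnover through the occupancy factor D34
    d[..., 1] = (
        (p.k0_sm + p.k_sm * act_T)
        * _hr(O, p.J_OT, p.n_OT)
        * _hr(S, p.J_ss, p.n_ss)
        - p.kd_sm * sm * D34
    )
    # SNAIL protein: translation silenced by miR-34a
    d[..., 2] = p.k_S * sm * L34 - p.kd_S * S
    # miR-34a: repressed by SNAIL (J1_34) and ZEB
    d[..., 3] = (
        p.k0_34
        + p.k_34 * _hr(S, p.J1_34, p.n1_34) * _hr(Z, p.J2_34, p.n2_34)
        - p.kd_34 * m34
    )
    # zeb1 mRNA: SNAIL-activated transcription repressed by OVOL2 (J_O);
    # constitutive basal term; turnover accelerated by miR-200
    d[..., 4] = (
        p.k0_zm
        + p.k_zm * act_S * _hr(O, p.J_O, p.n_O)
        - p.kd_zm * zm * D200
    )
    # ZEB protein: translation silenced by miR-200
    d[..., 5] = p.k_Z * zm * L200 - p.kd_Z * Z
    # miR-200: repressed by SNAIL and ZEB (J2_200)
    d[..., 6] = (
        p.k0_200
        + p.k_200 * _hr(S, p.J1_200, p.n1_200) * _hr(Z, p.J2_200, p.n2_200)
        - p.kd_200 * m200
    )
    # OVOL2: basal production repressed by ZEB, with a small
    # ZEB-independent leak fraction
    d[..., 7] = (
        p.ovol2_basal * (p.leak_O + (1.0 - p.leak_O) * _hr(Z, p.J2_zeb, p.n_zeb))
        - p.kd_O * O
    )
    # E-cadherin: repressed by SNAIL and ZEB
    d[..., 8] = (
        p.k0_E + p.k_E * _hr(S, p.J_es, p.n_es) * _hr(Z, p.J_ez, p.n_ez)
        - p.kd_E * E
    )
    # Vimentin: activated by SNAIL/ZEB (OR-gate), repressed by OVOL2
    d[..., 9] = (
        p.k0_V
        + p.k_V
        * (1.0 - _hr(S, p.J_vs, p.n_vs) * _hr(Z, p.J_vz, p.n_vz))
        * _hr(O, p.J_vo, p.n_vo)
        - p.kd_V * V
    )
    return d


def jacobian(x, params: ParameterSet, rel_step: float = 1e-6, floor: float = 1e-6):
    """Jacobian of :func:`rhs` by central finite differences.

    Per-species step ``max(|x_j|, floor) * rel_step``.  Broadcasts over
    leading axes: input ``(..., 10)`` gives output ``(..., 10, 10)``.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape + (N_SPECIES,), dtype=float)
    for j in range(N_SPECIES):
        h = np.maximum(np.abs(x[..., j]), floor) * rel_step
        xp = x.copy()
        xm = x.copy()
        xp[..., j] = x[..., j] + h
        xm[..., j] = np.maximum(x[..., j] - h, 0.0)
        dh = xp[..., j] - xm[..., j]
        # out[..., a, j] = d f_a / d x_j
        out[..., j] = (rhs(xp, params) - rhs(xm, params)) / dh[..., None]
    return out


# --------------------------------------------------------------------------
# Loop knockdowns (Table-style "x% SYMBOL" conditions)
# --------------------------------------------------------------------------

LOOPS = ("mir34_snail", "mir200_zeb", "ovol2_zeb")

#: knockdown symbol -> (parameter field, mode); "direct" multiplies the
#: parameter by the fraction, "inverse" (the 1/J symbols) divides it, so
#: that scaling "1/J" by a small fraction weakens the Hill repression.
KNOCKDOWN_SYMBOLS: dict[str, tuple[str, str]] = {
    "K_SR": ("K_SR", "direct"),
    "K_1": ("K_1", "direct"),
    "1/J1_34": ("J1_34", "inverse"),
    "1/J2_200": ("J2_200", "inverse"),
    "1/J_O": ("J_O", "inverse"),
    "1/J2_zeb": ("J2_zeb", "inverse"),
    "J1_34": ("J1_34", "direct"),
    "J2_200": ("J2_200", "direct"),
    "J_O": ("J_O", "direct"),
    "J2_zeb": ("J2_zeb", "direct"),
}


def apply_loop_knockdown(
    params: ParameterSet,
    loop: str,
    scaling: Mapping[str, float],
) -> ParameterSet:
    """Scale mutual-inhibition-loop parameters by the given fractions.

    ``scaling`` maps knockdown symbols (``"K_SR"``, ``"1/J1_34"``,
    ``"K_1"``, ``"1/J2_200"``, ``"1/J_O"``, ``"1/J2_zeb"``; bare ``J``
    names are also accepted) to fractions in (0, 1].  A ``"K"`` symbol
    multiplies the silencing strength by the fraction; a ``"1/J"``
    symbol multiplies the corresponding half-saturation constant by the
    reciprocal, weakening that Hill repression.  Returns a new
    parameter set; the input is unchanged.
    """
    if loop not in LOOPS:
        raise ParameterError(f"unknown loop {loop!r}; expected one of {LOOPS}")
    changes: dict[str, float] = {}
    for symbol, fraction in scaling.items():
        if symbol not in KNOCKDOWN_SYMBOLS:
            raise ParameterError(
                f"unknown knockdown symbol {symbol!r}; "
                f"known: {sorted(KNOCKDOWN_SYMBOLS)}"
            )
        if not (0 < fraction <= 1):
            raise ParameterError(
                f"knockdown fraction for {symbol!r} must be in (0, 1], got {fraction}"
            )
        field, mode = KNOCKDOWN_SYMBOLS[symbol]
        base = changes.get(field, getattr(params, field))
        changes[field] = base * fraction if mode == "direct" else base / fraction
    return params.replace(**changes)


# --------------------------------------------------------------------------
# Influence graph
# --------------------------------------------------------------------------

def influence_edges() -> dict[tuple[str, str], int]:
    """Signed gene-level influence graph: ``(source, target) -> ±1``.

    Nodes are regulators (mRNA/protein collapsed per gene); edges follow
    the wiring of :func:`rhs`.
    """
    return {
        ("TGFB", "SNAIL"): +1,
        ("SNAIL", "SNAIL"): -1,
        ("OVOL2", "SNAIL"): -1,   # attenuation of TGF-β signalling
        ("SNAIL", "MIR34"): -1,
        ("ZEB", "MIR34"): -1,
        ("MIR34", "SNAIL"): -1,
        ("SNAIL", "ZEB"): +1,
        ("OVOL2", "ZEB"): -1,
        ("SNAIL", "MIR200"): -1,
        ("ZEB", "MIR200"): -1,
        ("MIR200", "ZEB"): -1,
        ("ZEB", "OVOL2"): -1,
        ("MIR200", "TGFB"): -1,
        ("SNAIL", "ECAD"): -1,
        ("ZEB", "ECAD"): -1,
        ("SNAIL", "VIM"): +1,
        ("ZEB", "VIM"): +1,
        ("OVOL2", "VIM"): -1,
    }


def count_mutual_inhibition_loops(edges: Mapping[tuple[str, str], int] | None = None) -> int:
    """Number of unordered node pairs joined by mutually repressive edges."""
    if edges is None:
        edges = influence_edges()
    loops = set()
    for (a, b), sign in edges.items():
        if a == b or sign >= 0:
            continue
        if edges.get((b, a), 0) < 0:
            loops.add(frozenset((a, b)))
    return len(loops)


# --------------------------------------------------------------------------
# Deterministic integration helper
# --------------------------------------------------------------------------

def integrate(
    params: ParameterSet,
    x0,
    t_end: float,
    t_eval: Iterable[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate the ODE with scipy's LSODA; returns ``(t, states)``.

    States are clipped at zero only through the solver's error control;
    a non-finite result raises :class:`IntegrationError`.
    """
    from scipy.integrate import solve_ivp

    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0) or not np.all(np.isfinite(x0)):
        raise ParameterError("initial condition must be finite and non-negative")

    def f(t, y):
        return rhs(np.maximum(y, 0.0), params, t=t)

    sol = solve_ivp(
        f, (0.0, float(t_end)), x0,
        method="LSODA",
        t_eval=None if t_eval is None else np.asarray(list(t_eval), dtype=float),
        rtol=rtol, atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"integration failed: {sol.message}", sol.t[-1] if len(sol.t) else None)
    return sol.t, np.maximum(sol.y.T, 0.0)
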