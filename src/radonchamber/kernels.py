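"""Closed-form activity concentrations under constant source and filtration.

The model: a gas (Rn-222 or Rn-220) flows into a volume ``V`` at a constant
rate ``E1`` (Bq/s) and decays through its sub-series; aerosol-attached progeny
are additionally removed by a filtering device of efficiency ``F`` drawing air
at flow ``Q_D``, giving a first-order removal rate ``R_D = F*Q_D/V``.  The
governing linear system is::

    dC1/dt = S1 - lambda_1 * C1                      (gas, S1 = E1/V)
    dCi/dt = -(R_D + lambda_i) * Ci + eps_i * lambda_i * C_{i-1}   (i > 1)

Because the system is a linear cascade with constant coefficients, each
concentration has an exact closed form: a Bateman-type sum of exponentials
``exp(-mu_p t)`` with effective rates ``mu_1 = lambda_1`` (the noble gas is
not filtered) and ``mu_i = lambda_i + R_D`` for progeny, plus a particular
term driven by the source.  Evaluation is vectorized over a time grid and
carries no stepping error.

Denominators of the form ``lambda_i - lambda_1 + R_D`` can vanish for the
thoron chain at specific device flows (the underlying ODE stays perfectly
regular; only this representation degenerates).  A guard detects
near-singular denominators and transparently switches to the numerical
reference engine for that query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nuclear_data import DecayChain, Nuclide

__all__ = [
    "SystemParameters",
    "ChainState",
    "concentrations_at",
    "bateman",
    "constant_parent",
    "steady_state",
    "singular_guard",
    "SingularityReport",
    "SINGULAR_GUARD_REL",
]

#: a denominator |mu_q - mu_p| is treated as singular below this fraction of
#: the larger decay constant involved; catastrophic cancellation sets in well
#: below this scale, so the guarded query falls back to the numerical engine
SINGULAR_GUARD_REL = 1e-9

L_PER_MIN_TO_M3_PER_S = 1.0 / 60000.0


@dataclass(frozen=True)
class SystemParameters:
    """Chamber and device parameters.

    Attributes
    ----------
    V : float
        Chamber volume, m^3.
    E1 : float
        Gas inflow rate, Bq/s.
    Q_D : float
        Device flow rate, m^3/s.
    F : float
        Filtration efficiency, 0-1.
    """

    V: float
    E1: float = 0.0
    Q_D: float = 0.0
    F: float = 0.0

    def __post_init__(self) -> None:
        for label, x in (("V", self.V), ("E1", self.E1), ("Q_D", self.Q_D), ("F", self.F)):
            if not math.isfinite(x):
                raise ValueError(f"{label} must be finite, got {x}")
        if self.V <= 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        if self.E1 < 0 or self.Q_D < 0:
            raise ValueError("E1 and Q_D must be >= 0")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must lie in [0, 1], got {self.F}")

    @property
    def S1(self) -> float:
        """Source density E1/V, Bq m^-3 s^-1."""
        return self.E1 / self.V

    @property
    def R_D(self) -> float:
        """Progeny removal rate F*Q_D/V, s^-1."""
        return self.F * self.Q_D / self.V

    @classmethod
    def with_device(
        cls, V: float, E1: float = 0.0, flow_L_per_min: float = 0.0, F: float = 0.0
    ) -> "SystemParameters":
        """Convenience constructor taking the device flow in L/min."""
        return cls(V=V, E1=E1, Q_D=flow_L_per_min * L_PER_MIN_TO_M3_PER_S, F=F)


@dataclass(frozen=True)
class ChainState:
    """Per-nuclide activity concentrations (Bq/m^3) aligned with chain.members."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("state must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("state contains non-finite entries")
        if np.any(v < 0):
            raise ValueError("activity concentrations must be >= 0")
        object.__setattr__(self, "values", v)

    @classmethod
    def zeros(cls, chain: DecayChain) -> "ChainState":
        return cls(np.zeros(len(chain)))

    @classmethod
    def from_mapping(cls, chain: DecayChain, mapping: dict[str, float]) -> "ChainState":
        v = np.zeros(len(chain))
        for name, c in mapping.items():
            v[chain.index(name)] = c
        return cls(v)

    @classmethod
    def gas_only(cls, chain: DecayChain, c1: float) -> "ChainState":
        return cls.from_mapping(chain, {chain.gas.name: c1})


@dataclass(frozen=True)
class SingularityReport:
    """Near-singular closed-form denominators for a parameter set.

    ``flagged`` lists ``(name_i, name_j, value)`` triples where the
    denominator ``mu_i - mu_j`` falls below the guard threshold.
    """

    flagged: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    @property
    def must_fallback(self) -> bool:
        return len(self.flagged) > 0


def _effective_rates(chain: DecayChain, R_D: float) -> np.ndarray:
    """mu_i for every member: lambda_1 for the gas, lambda_i + R_D for progeny."""
    return np.array(
        [n.decay_constant + (0.0 if n.parent is None else R_D) for n in chain.members]
    )


def singular_guard(chain: DecayChain, params: SystemParameters) -> SingularityReport:
    """Diagnose near-singular denominators |mu_i - mu_j| for these parameters.

    For the radon chain every progeny decay constant exceeds the gas's, so
    ``lambda_i - lambda_1 + R_D > 0`` always and the report is empty.  For
    thoron, specific device flows make ``R_D = lambda_1 - lambda_i`` for
    i in {Pb-212, Bi-212, Tl-208}.
    """
    mus = _effective_rates(chain, params.R_D)
    lams = np.array([n.decay_constant for n in chain.members])
    flagged = []
    for i in range(len(chain)):
        for j in range(i + 1, len(chain)):
            # branch siblings never share a path, so their difference is
            # never a denominator
            if chain.members[i].chain_index == chain.members[j].chain_index:
                continue
            if abs(mus[i] - mus[j]) < SINGULAR_GUARD_REL * max(lams[i], lams[j]):
                flagged.append(
                    (chain.members[i].name, chain.members[j].name, float(mus[i] - mus[j]))
                )
    return SingularityReport(flagged=tuple(flagged))


def _source_integral(mu: float, t: np.ndarray) -> np.ndarray:
    """Integral of exp(-mu*s) over [0, t]: (1 - exp(-mu t))/mu, = t at mu = 0."""
    if mu == 0.0:
        return t.copy()
    return -np.expm1(-mu * t) / mu


def _path_solution(
    mus: np.ndarray, ks: np.ndarray, c0: np.ndarray, s1: float, t: np.ndarray
) -> np.ndarray:
    """Exact solution for the last member of a linear cascade.

    ``mus`` are the effective removal rates along the path, ``ks[m]`` the
    production coefficients eps_m * lambda_m (ks[0] unused), ``c0`` the
    initial concentrations along the path, ``s1`` the constant source into
    compartment 0.  Returns C_last(t) on the grid ``t``.
    """
    n = len(mus)
    i = n - 1
    out = np.zeros_like(t)
    # homogeneous part: contribution of each ancestor's initial concentration
    for j in range(n):
        if c0[j] == 0.0:
            continue
        coef = c0[j] * np.prod(ks[j + 1 : i + 1])
        acc = np.zeros_like(t)
        for p in range(j, i + 1):
            denom = np.prod([mus[q] - mus[p] for q in range(j, i + 1) if q != p])
            acc += np.exp(-mus[p] * t) / denom
        out += coef * acc
    # particular part: constant source feeding compartment 0
    if s1 != 0.0:
        coef = s1 * np.prod(ks[1 : i + 1])
        acc = np.zeros_like(t)
        for p in range(i + 1):
            denom = np.prod([mus[q] - mus[p] for q in range(i + 1) if q != p])
            acc += _source_integral(mus[p], t) / denom
        out += coef * acc
    return out


def _validate_time(t) -> tuple[np.ndarray, bool]:
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("time contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("time must be >= 0")
    return arr, np.ndim(t) == 0


def concentrations_at(
    chain: DecayChain,
    params: SystemParameters,
    state0: ChainState,
    t,
    *,
    check_singular: bool = True,
) -> np.ndarray:
    """Activity concentrations C_i(t) (Bq/m^3) for every chain member.

    Exact solution of the constant-coefficient cascade for the given source
    ``S1`` and removal rate ``R_D``; the gas concentration is independent of
    ``R_D``.  ``t`` may be a scalar or an array; the result has shape
    ``(len(chain),)`` or ``(len(t), len(chain))`` accordingly, ordered as
    ``chain.members``.

    If the parameters sit inside the singular guard band (thoron chain at a
    critical device flow) the query is evaluated with the numerical reference
    engine instead of the degenerate closed form.
    """
    tgrid, scalar = _validate_time(t)
    if len(state0.values) != len(chain):
        raise ValueError("initial state length does not match chain")

    if check_singular and singular_guard(chain, params).must_fallback:
        from . import oracle

        out = oracle.integrate(chain, params, state0, tgrid, engine="expm")
        return out[0] if scalar else out

    mus = _effective_rates(chain, params.R_D)
    out = np.empty((len(tgrid), len(chain)))
    for i in range(len(chain)):
        path = chain.path_to(i)
        pm = mus[list(path)]
        pk = np.array(
            [0.0] + [chain.members[p].branch_in * chain.members[p].decay_constant
                     for p in path[1:]]
        )
        pc0 = state0.values[list(path)]
        out[:, i] = _path_solution(pm, pk, pc0, params.S1, tgrid)
    out[tgrid == 0.0] = state0.values  # initial condition holds exactly
    np.maximum(out, 0.0, out=out)  # clip roundoff-negative values
    return out[0] if scalar else out


def bateman(chain: DecayChain, state0: ChainState, t) -> np.ndarray:
    """Classic Bateman decay of an initial mixture: no source, no filtration.

    Identical to :func:`concentrations_at` with ``S1 = 0`` and ``R_D = 0``.
    """
    return concentrations_at(chain, SystemParameters(V=1.0), state0, t)


def constant_parent(chain: DecayChain, state0: ChainState, t) -> np.ndarray:
    """Progeny ingrowth under a gas concentration held exactly constant.

    Models inflow that compensates the gas's decay completely: C1(t) = C_o1
    for all t, and each progeny grows toward ``eps``-weighted equality with
    the gas.  Because the gas no longer decays on the chain's timescale, even
    the thoron series reaches a true equilibrium in this regime.
    """
    tgrid, scalar = _validate_time(t)
    if len(state0.values) != len(chain):
        raise ValueError("initial state length does not match chain")
    # same cascade with the gas's decay constant replaced by zero (no source,
    # no filtration); production coefficients of progeny are unchanged
    mus = _effective_rates(chain, 0.0)
    mus[0] = 0.0
    out = np.empty((len(tgrid), len(chain)))
    for i in range(len(chain)):
        path = chain.path_to(i)
        pm = mus[list(path)]
        pk = np.array(
            [0.0] + [chain.members[p].branch_in * chain.members[p].decay_constant
                     for p in path[1:]]
        )
        pc0 = state0.values[list(path)]
        out[:, i] = _path_solution(pm, pk, pc0, 0.0, tgrid)
    out[tgrid == 0.0] = state0.values
    np.maximum(out, 0.0, out=out)
    return out[0] if scalar else out


def steady_state(chain: DecayChain, params: SystemParameters) -> np.ndarray:
    """Asymptotic concentrations under constant inflow and filtration.

    ``C1 = S1/lambda_1`` for the gas and
    ``C_i = eps_i * lambda_i * C_parent / (lambda_i + R_D)`` down the chain;
    this is the t -> infinity limit of :func:`concentrations_at`.  With
    ``E1 = 0`` everything decays away and the zero state is returned.
    """
    out = np.zeros(len(chain))
    if params.E1 == 0.0:
        return out
    out[0] = params.S1 / chain.gas.decay_constant
    pos = {n.name: k for k, n in enumerate(chain.members)}
    for k, n in enumerate(chain.members):
        if n.parent is None:
            continue
        out[k] = n.branch_in * n.decay_constant * out[pos[n.parent]] / (
            n.decay_constant + params.R_D
        )
    return out
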