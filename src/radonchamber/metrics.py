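"""Derived radiometric quantities.

Potential alpha energy concentration (PAEC) and per-nuclide shares,
equilibrium factor, times to reach a fraction of the asymptote, and the
critical device flows that make the thoron closed forms singular.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .kernels import ChainState, SystemParameters, concentrations_at, steady_state
from .nuclear_data import DecayChain, potential_alpha_energy_per_bq

__all__ = [
    "PAECResult",
    "paec",
    "paec_coefficients",
    "paec_series",
    "equilibrium_factor",
    "equilibrium_factor_series",
    "time_to_fraction",
    "critical_flows",
    "GAS_APPROACH_FRACTION",
    "CHAIN_EQUILIBRATION_FRACTION",
]

#: fraction of the asymptote at which the gas concentration is considered to
#: have "reached" steady state (~40 d for radon, ~10 min for thoron)
GAS_APPROACH_FRACTION = 0.999

#: fraction of the asymptote used for progeny/chain equilibration times
#: (~3-4 h for radon progeny, ~70 h for the Pb-212-limited thoron chain)
CHAIN_EQUILIBRATION_FRACTION = 0.99


@dataclass(frozen=True)
class PAECResult:
    """PAEC split by nuclide.  ``shares`` are zero (with ``defined=False``)
    when the total vanishes."""

    total: float
    per_nuclide: dict[str, float]
    shares: dict[str, float]
    defined: bool


@lru_cache(maxsize=None)
def paec_coefficients(chain: DecayChain) -> np.ndarray:
    """E_p/lambda coefficients (J/Bq) aligned with chain.members; 0 for the gas."""
    return np.array(
        [0.0 if n.parent is None else potential_alpha_energy_per_bq(n, chain)
         for n in chain.members]
    )


def paec(chain: DecayChain, C: np.ndarray) -> PAECResult:
    """Potential alpha energy concentration (J/m^3) of a concentration vector.

    Each progeny contributes ``C_i * E_p,i / lambda_i``; the gas is excluded.
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (len(chain),):
        raise ValueError("concentration vector length does not match chain")
    if np.any(C < 0) or not np.all(np.isfinite(C)):
        raise ValueError("concentrations must be finite and >= 0")
    coeff = paec_coefficients(chain)
    per = C * coeff
    total = float(per.sum())
    progeny = [(n.name, float(per[k])) for k, n in enumerate(chain.members) if n.parent]
    if total > 0:
        shares = {name: v / total for name, v in progeny}
        defined = True
    else:
        shares = {name: 0.0 for name, _ in progeny}
        defined = False
    return PAECResult(total=total, per_nuclide=dict(progeny), shares=shares, defined=defined)


def paec_series(chain: DecayChain, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized PAEC for a (T, n) concentration array.

    Returns ``(totals, shares)`` with shares shaped (T, n) — zero columns for
    the gas, and all-zero rows where the total vanishes.
    """
    coeff = paec_coefficients(chain)
    per = np.asarray(C, dtype=float) * coeff
    totals = per.sum(axis=1)
    shares = np.zeros_like(per)
    nz = totals > 0
    shares[nz] = per[nz] / totals[nz, None]
    return totals, shares


def _secular_reference_total(chain: DecayChain, c1: float) -> float:
    # reference: every progeny activity equal to the gas's
    coeff = paec_coefficients(chain)
    return c1 * float(coeff.sum())


def equilibrium_factor(chain: DecayChain, C: np.ndarray) -> float:
    """Ratio of actual PAEC to the PAEC at secular equilibrium with the gas.

    The reference state sets every progeny activity equal to the gas
    concentration C1, so the factor is 1 at full equilibrium and 0 for pure
    gas.  Undefined for C1 = 0.
    """
    C = np.asarray(C, dtype=float)
    if C[0] <= 0:
        raise ValueError("equilibrium factor is undefined for zero gas concentration")
    return paec(chain, C).total / _secular_reference_total(chain, C[0])


def equilibrium_factor_series(chain: DecayChain, C: np.ndarray) -> np.ndarray:
    """Per-row equilibrium factor for a (T, n) array; NaN where C1 = 0."""
    C = np.asarray(C, dtype=float)
    totals, _ = paec_series(chain, C)
    ref = C[:, 0] * float(paec_coefficients(chain).sum())
    out = np.full(len(C), np.nan)
    nz = ref > 0
    out[nz] = totals[nz] / ref[nz]
    return out


def time_to_fraction(
    chain: DecayChain,
    params: SystemParameters,
    state0: ChainState,
    target: float,
    which: str,
    *,
    t_max: float = 1e10,
) -> float:
    """Smallest time (s) at which ``C_which(t)`` reaches ``target`` times its
    steady-state value.

    For the gas starting from zero this reduces to ``-ln(1-target)/lambda_1``
    and is independent of the inflow rate and the chamber volume.  A
    non-monotone approach (possible after large injections) is handled by
    returning the first crossing, with a warning.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target must lie strictly between 0 and 1")
    idx = chain.index(which)
    c_inf = steady_state(chain, params)[idx]
    if c_inf <= 0:
        raise ValueError(f"steady-state concentration of {which} is zero; no asymptote")

    def ratio(t: float) -> float:
        return float(concentrations_at(chain, params, state0, t)[idx]) / c_inf

    if ratio(0.0) >= target:
        return 0.0
    # bracket the first crossing by doubling from the nuclide's half-life scale
    t_hi = chain.members[idx].half_life / 64.0
    while ratio(t_hi) < target:
        t_hi *= 2.0
        if t_hi > t_max:
            raise RuntimeError(f"{which} does not reach {target} of asymptote by {t_max} s")
    t_lo = t_hi / 2.0 if t_hi > chain.members[idx].half_life / 64.0 else 0.0
    # locate the first sign change on a fine grid so a non-monotone approach
    # still yields the first crossing
    grid = np.linspace(t_lo, t_hi, 65)
    vals = concentrations_at(chain, params, state0, grid)[:, idx] / c_inf
    if np.any(np.diff(vals) < -1e-12 * max(1.0, float(np.max(np.abs(vals))))):
        warnings.warn(f"non-monotone approach for {which}; returning first crossing",
                      RuntimeWarning, stacklevel=2)
    k = int(np.argmax(vals >= target))
    a, b = (grid[k - 1], grid[k]) if k > 0 else (t_lo, t_hi)
    return float(brentq(lambda t: ratio(t) - target, a, b, rtol=1e-9))


def critical_flows(chain: DecayChain, V: float, F: float) -> dict[str, float]:
    """Device flows (L/min) that make a closed-form denominator vanish.

    A denominator ``lambda_i - lambda_1 + R_D`` is zero when
    ``Q = V (lambda_1 - lambda_i)/F``, possible only for chain members whose
    decay constant is below the gas's — Pb-212, Bi-212 and Tl-208 in the
    thoron chain, and never for radon.  Returns an empty mapping for the
    radon chain or for F = 0 (no finite critical flow).
    """
    if V <= 0:
        raise ValueError("V must be > 0")
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    if F == 0.0:
        return {}
    lam1 = chain.gas.decay_constant
    out = {}
    for n in chain.progeny:
        if n.decay_constant < lam1:
            q_m3_s = V * (lam1 - n.decay_constant) / F
            out[n.name] = q_m3_s * 60000.0  # m^3/s -> L/min
    return out
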