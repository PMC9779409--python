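"""Bundled nuclear constants and decay-chain definitions.

The package models the two short-lived decay sub-series relevant to indoor
air monitoring:

* radon:  Rn-222 -> Po-218 -> Pb-214 -> Bi-214 -> Po-214
* thoron: Rn-220 -> Po-216 -> Pb-212 -> Bi-212 -> {Po-212 (63.8%),
  Tl-208 (36.2%)}

Each chain member carries its decay constant, the branch fraction feeding it,
and the alpha energy emitted per decay.  Potential-alpha-energy coefficients
(J per Bq of airborne activity) are derived from these at load time rather
than hardcoded, so they always track the half-life table.

Half-lives follow ICRP Publication 107; the table ships as a plain CSV inside
the package (``data/nuclides.csv``) so it can be audited and round-tripped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "Nuclide",
    "DecayChain",
    "load_chain",
    "load_nuclide_table",
    "potential_alpha_energy_per_bq",
    "SUPPORTED_GASES",
]

LN2 = math.log(2.0)

#: conversion factor, 1 MeV in joules (CODATA exact)
MEV_TO_J = 1.602176634e-13

SUPPORTED_GASES = ("Rn-222", "Rn-220")


class UnsupportedChainError(ValueError):
    """Raised when a decay chain outside the bundled catalog is requested."""


@dataclass(frozen=True)
class Nuclide:
    """One decay-chain member.

    Parameters
    ----------
    name : str
        Nuclide label, e.g. ``"Pb-212"``.
    half_life : float
        Half-life in seconds.
    branch_in : float
        Fraction of the parent's decays feeding this nuclide (1 except for
        the Bi-212 branch members Po-212 and Tl-208).
    alpha_energy : float
        Alpha energy emitted per decay of this nuclide, MeV (branch-weighted
        expectation for Bi-212; 0 for pure beta/gamma emitters).
    chain_index : int
        Conventional position 1-5 in the sub-series; the two parallel
        terminal branch members share index 5.
    parent : str or None
        Name of the nuclide feeding this one (None for the gas).
    """

    name: str
    half_life: float
    branch_in: float
    alpha_energy: float
    chain_index: int
    parent: str | None

    @property
    def decay_constant(self) -> float:
        """Decay constant lambda = ln(2)/half_life, s^-1."""
        return LN2 / self.half_life

    def __post_init__(self) -> None:
        if not (self.half_life > 0 and math.isfinite(self.half_life)):
            raise ValueError(f"{self.name}: half-life must be positive and finite")
        if not 0.0 < self.branch_in <= 1.0:
            raise ValueError(f"{self.name}: branch fraction must lie in (0, 1]")
        if self.alpha_energy < 0.0:
            raise ValueError(f"{self.name}: alpha energy must be >= 0")


@dataclass(frozen=True)
class DecayChain:
    """An ordered decay sub-series starting at the noble gas.

    ``members`` lists every nuclide including the gas; for the thoron chain
    the last two entries are the parallel Bi-212 branch members Po-212 and
    Tl-208 (both chain_index 5, branch fractions summing to 1).
    """

    gas: Nuclide
    members: tuple[Nuclide, ...]

    @property
    def progeny(self) -> tuple[Nuclide, ...]:
        return self.members[1:]

    @property
    def branch_members(self) -> tuple[Nuclide, ...]:
        """The parallel terminal members at chain index 5 (empty for radon)."""
        at5 = tuple(n for n in self.members if n.chain_index == 5)
        return at5 if len(at5) > 1 else ()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def index(self, name: str) -> int:
        """Position of ``name`` in ``members`` (0-based)."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"{name!r} is not a member of the {self.gas.name} chain") from None

    def path_to(self, i: int) -> tuple[int, ...]:
        """0-based member positions along the linear ancestry gas -> member i.

        For the thoron branch members this skips the sibling branch, so the
        returned path is always a strict linear chain.
        """
        pos = {n.name: k for k, n in enumerate(self.members)}
        path = [i]
        while self.members[path[-1]].parent is not None:
            path.append(pos[self.members[path[-1]].parent])
        return tuple(reversed(path))

    def children(self, name: str) -> tuple[Nuclide, ...]:
        return tuple(n for n in self.members if n.parent == name)


def load_nuclide_table() -> pd.DataFrame:
    """Read the bundled nuclear-data CSV as a DataFrame (one row per nuclide)."""
    with resources.files("radonchamber").joinpath("data/nuclides.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def _build_chain(table: pd.DataFrame, gas_name: str) -> DecayChain:
    rows = []
    frontier = [gas_name]
    by_name = table.set_index("name")
    while frontier:
        name = frontier.pop(0)
        row = by_name.loc[name]
        rows.append(
            Nuclide(
                name=name,
                half_life=float(row["half_life_s"]),
                branch_in=float(row["branch_in"]),
                alpha_energy=float(row["alpha_energy_MeV"]),
                chain_index=int(row["chain_index"]),
                parent=None if pd.isna(row["parent"]) else str(row["parent"]),
            )
        )
        frontier.extend(table.loc[table["parent"] == name, "name"].tolist())
    return DecayChain(gas=rows[0], members=tuple(rows))


def load_chain(gas_name: str) -> DecayChain:
    """Return the fully populated decay chain for ``"Rn-222"`` or ``"Rn-220"``.

    Raises
    ------
    UnsupportedChainError
        If ``gas_name`` is not one of the two bundled sub-series.
    """
    if gas_name not in SUPPORTED_GASES:
        raise UnsupportedChainError(
            f"unsupported chain {gas_name!r}; available: {', '.join(SUPPORTED_GASES)}"
        )
    return _build_chain(load_nuclide_table(), gas_name)


def _total_alpha_energy(chain: DecayChain, nuclide: Nuclide) -> float:
    """Expected alpha energy (MeV) emitted by one atom of ``nuclide`` and all
    its descendants down to the chain terminus, weighted by branch fractions."""
    total = nuclide.alpha_energy
    for child in chain.children(nuclide.name):
        total += child.branch_in * _total_alpha_energy(chain, child)
    return total


def potential_alpha_energy_per_bq(nuclide: Nuclide, chain: DecayChain) -> float:
    """Potential-alpha-energy coefficient E_p/lambda in J per Bq.

    One becquerel of airborne ``nuclide`` corresponds to ``1/lambda`` atoms;
    each atom will eventually emit ``E_p`` of alpha energy, summed over the
    nuclide's own decay and every descendant down to the stable terminus
    (branch-weighted).  The noble gas itself is excluded from PAEC accounting
    by convention — unattached gas atoms are not retained in the lung the way
    aerosol-borne progeny are.

    Raises
    ------
    ValueError
        If the gas nuclide is passed.
    """
    if nuclide.name == chain.gas.name:
        raise ValueError("the gas is excluded from potential-alpha-energy accounting")
    if nuclide.name not in chain.names:
        raise KeyError(f"{nuclide.name!r} is not a member of the {chain.gas.name} chain")
    e_p_mev = _total_alpha_energy(chain, nuclide)
    return e_p_mev * MEV_TO_J / nuclide.decay_constant
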