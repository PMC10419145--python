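"""Mapping between hydrolysis time and degree of hydrolysis.

The degree of hydrolysis ``d`` is the percentage of all backbone peptide
bonds cleaved.  The model-internal map advances every kinetically active
enzyme-specific bond by its own mechanism (one-stage demask-then-cleave, or
the two-stage series chain) and averages over all backbone bonds:

    d(t) = 100 / N_total * sum_b f_b(t)

with ``f_b`` the hydrolyzed fraction of bond ``b``.  For beta-LG this uses
the 13 active sites out of 161 backbone bonds, so ``d`` saturates at
``d_max = 13/161 * 100 = 8.07 %``.  The map is strictly increasing and is
inverted numerically, which lets any concentration-versus-time curve be
re-expressed on a degree grid by re-evaluating the closed forms at
``t = t(d)`` (no interpolation of sampled curves).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import ConcentrationCurve, KineticsError, bond_hydrolysis_fraction
from .substrate import KD_DEFAULT, KDF_DEFAULT, SubstrateMap


class DegreeError(ValueError):
    """Raised for invalid degree values or inventories."""


@dataclass(frozen=True)
class InventoryBond:
    """One kinetically active bond inside a :class:`BondInventory`."""

    key: int
    label: str
    mechanism: str
    k_abs: float

    def __post_init__(self) -> None:
        if self.k_abs <= 0:
            raise DegreeError(f"bond {self.label}: inventory bonds need k_abs > 0")
        if self.mechanism not in ("one_stage", "two_stage"):
            raise DegreeError(f"bond {self.label}: unknown mechanism")


@dataclass(frozen=True)
class BondInventory:
    """The active-bond census that defines the time -> degree map."""

    bonds: tuple[InventoryBond, ...]
    total_bonds: int
    kdf: float = KDF_DEFAULT
    kd: float = KD_DEFAULT

    def __post_init__(self) -> None:
        if self.total_bonds < len(self.bonds):
            raise DegreeError("total_bonds must be >= number of included bonds")

    @property
    def d_max(self) -> float:
        """Asymptotic degree of hydrolysis, %."""
        return 100.0 * len(self.bonds) / self.total_bonds

    @classmethod
    def from_substrate_map(
        cls,
        substrate: SubstrateMap,
        overrides: Mapping[int, float] | None = None,
        *,
        kdf: float = KDF_DEFAULT,
        kd: float = KD_DEFAULT,
    ) -> "BondInventory":
        """Inventory of all non-excluded sites, with optional per-bond rates.

        ``overrides`` (bond index -> min^-1) replaces the table-derived
        ``k_abs`` for individual bonds, e.g. with the fitted constants used
        in a simulation study.
        """
        overrides = dict(overrides or {})
        bonds = []
        for site in substrate.sites:
            k = float(overrides.get(site.bond_index, site.k_abs))
            if site.demask_class == "excluded" or k <= 0:
                continue
            bonds.append(
                InventoryBond(site.bond_index, site.label, site.demask_class, k)
            )
        return cls(
            bonds=tuple(bonds), total_bonds=substrate.total_bonds, kdf=kdf, kd=kd
        )

    def without(self, key: int) -> "BondInventory":
        return BondInventory(
            bonds=tuple(b for b in self.bonds if b.key != key),
            total_bonds=self.total_bonds,
            kdf=self.kdf,
            kd=self.kd,
        )


def degree_of_hydrolysis(inventory: BondInventory, t) -> np.ndarray | float:
    """Degree of hydrolysis (%) at time ``t`` (min), vectorized."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DegreeError("t must be >= 0")
    total = np.zeros_like(t_arr)
    for bond in inventory.bonds:
        total += bond_hydrolysis_fraction(
            bond.mechanism,
            inventory.kdf,
            bond.k_abs,
            t_arr,
            kd=inventory.kd if bond.mechanism == "two_stage" else None,
        )
    d = 100.0 * total / inventory.total_bonds
    return d if np.ndim(t) else float(d[0])


def invert_degree(inventory: BondInventory, d: float) -> float:
    """The hydrolysis time (min) at which the degree map reaches ``d`` %."""
    if d < 0:
        raise DegreeError("d must be >= 0")
    if d >= inventory.d_max:
        raise DegreeError(
            f"d = {d} % is unreachable: the inventory saturates at "
            f"d_max = {inventory.d_max:.4f} %"
        )
    if d == 0:
        return 0.0
    t_hi = 1.0
    while degree_of_hydrolysis(inventory, t_hi) < d:
        t_hi *= 2.0
        if t_hi > 1e12:  # pragma: no cover - d_max guard makes this unreachable
            raise DegreeError("failed to bracket the inversion")
    return brentq(
        lambda t: degree_of_hydrolysis(inventory, t) - d,
        0.0,
        t_hi,
        xtol=1e-12,
        rtol=8.9e-16,
    )


def times_for_degrees(inventory: BondInventory, d_grid) -> np.ndarray:
    """Vector of t(d) for a degree grid (%, within [0, d_max))."""
    return np.array([invert_degree(inventory, float(d)) for d in np.asarray(d_grid)])


@dataclass(frozen=True)
class DegreeMap:
    """A sampled monotone (t, d) table with its asymptote."""

    table: pd.DataFrame  # columns: t_min, d_pct
    d_max: float

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def degree_map(inventory: BondInventory, times) -> DegreeMap:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    d = degree_of_hydrolysis(inventory, t)
    return DegreeMap(
        table=pd.DataFrame({"t_min": t, "d_pct": d}), d_max=inventory.d_max
    )


def curve_on_degree_grid(
    concentration: Callable[[np.ndarray], np.ndarray],
    inventory: BondInventory,
    d_grid,
    *,
    species: str = "",
) -> ConcentrationCurve:
    """Re-express a concentration-versus-time function on a degree grid.

    ``concentration`` is the underlying closed-form function of time (see
    :func:`pepdemask.kinetics.concentration_functions`); it is re-evaluated
    at ``t = t(d)`` for each grid point.
    """
    d = np.atleast_1d(np.asarray(d_grid, dtype=float))
    if d.size > 1 and not np.all(np.diff(d) > 0):
        raise KineticsError("degree grid must be strictly increasing")
    values = concentration(times_for_degrees(inventory, d))
    return ConcentrationCurve(species or "curve", "degree", d, values)
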