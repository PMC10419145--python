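"""Closed-form release kinetics for masked trimeric blocks.

A trimeric block ABC sits between the most rapidly hydrolyzed bonds of the
chain and carries two internal enzyme-specific bonds, i (A|B) and j (B|C).
Under the one-stage mechanism the block is demasked in a single first-order
step (rate ``k_df``); under the two-stage mechanism a second step (rate
``k_d``) through a hydrolysis-resistant core precedes exposure.  Once
demasked, bonds i and j are cleaved with first-order rate constants ``k_i``
and ``k_j``, releasing the intermediates AB/BC and the final fragments
A/B/C.  All concentrations are relative: the initial concentration of every
block position is 1, so each species curve is a dimensionless fraction.

Every product concentration is a signed sum of exponentials
``C(t) = C0 + C1 e^(-kdf t) + C2 e^(-(ki+kj) t) + C3 e^(-kd t)
+ C4 e^(-ki t) + C5 e^(-kj t)`` (the ``kd`` term only for two-stage).  The
coefficients follow from integrating the first-order network species by
species; [B] is obtained through the block material balance, which is exact
by conservation.  Near rate coincidences the exponential algebra has
vanishing denominators, and evaluation is dispatched to the matrix
exponential of the network generator, which is division-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import expm

ONE_STAGE_SPECIES = ("masked", "ABC", "AB", "BC", "A", "B", "C")
TWO_STAGE_SPECIES = ("masked", "core", "ABC", "AB", "BC", "A", "B", "C")
PRODUCT_SPECIES = ("ABC", "AB", "BC", "A", "B", "C")

#: relative closeness of two rates below which the limit path is taken
DEGENERACY_RTOL = 1e-7


class KineticsError(ValueError):
    """Raised for invalid rate sets or evaluation grids."""


@dataclass(frozen=True)
class RateSet:
    """Rate constants (min^-1) driving one scheme instance.

    ``kd`` is the second demasking constant and is present only for the
    two-stage mechanism.
    """

    kdf: float
    ki: float
    kj: float
    kd: float | None = None

    def __post_init__(self) -> None:
        if self.kdf <= 0:
            raise KineticsError("kdf must be > 0")
        for name in ("ki", "kj"):
            value = getattr(self, name)
            if value < 0:
                raise KineticsError(f"{name} must be >= 0")
        if self.kd is not None and self.kd < 0:
            raise KineticsError("kd must be >= 0 when present")

    @property
    def mechanism(self) -> str:
        return "one_stage" if self.kd is None else "two_stage"

    def _require_hydrolyzable(self) -> None:
        if self.ki == 0 or self.kj == 0:
            raise KineticsError(
                "ki and kj must be > 0; treat a zero-rate bond as excluded "
                "and drop it from the scheme instead"
            )


@dataclass(frozen=True)
class ConcentrationCurve:
    """A species' relative concentration over time (min) or degree (%)."""

    species: str
    axis: str  # "time" or "degree"
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape:
            raise KineticsError("grid and values must be matching 1-d arrays")
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise KineticsError("grid must be strictly increasing")
        if self.axis not in ("time", "degree"):
            raise KineticsError(f"unknown axis {self.axis!r}")
        if np.any(values < -1e-9) or np.any(values > 1 + 1e-9):
            raise KineticsError(
                f"{self.species}: relative concentrations outside [0, 1]"
            )
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", np.clip(values, 0.0, None))


@dataclass(frozen=True)
class CoefficientSet:
    """Exponential-sum coefficients for one species of the two-stage scheme.

    ``coeffs[k]`` multiplies ``exp(-decay_rates[k] * t)`` with
    ``decay_rates = (0, kdf, ki + kj, kd, ki, kj)``.  The coefficients of
    every species sum to zero because all products start at concentration 0.
    """

    species: str
    coeffs: tuple[float, float, float, float, float, float]
    decay_rates: tuple[float, float, float, float, float, float]

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        out = np.zeros_like(t)
        for c, r in zip(self.coeffs, self.decay_rates):
            out += c * np.exp(-r * t)
        return out


def _check_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise KineticsError("times must be >= 0")
    return t


def _is_close(a: float, b: float) -> bool:
    return abs(a - b) <= DEGENERACY_RTOL * max(abs(a), abs(b))


def is_degenerate(rates: RateSet) -> bool:
    """Whether any denominator pair of the closed forms nearly vanishes."""
    k = rates
    total = k.ki + k.kj
    pairs = [(k.ki, k.kdf), (k.kj, k.kdf), (total, k.kdf)]
    if k.kd is not None:
        pairs += [(k.kd, k.kdf), (total, k.kd), (k.ki, k.kd), (k.kj, k.kd)]
    return any(_is_close(a, b) for a, b in pairs)


# -- matrix-exponential limit path --------------------------------------


def _generator(rates: RateSet) -> tuple[np.ndarray, tuple[str, ...]]:
    """Generator matrix G of the linear network, dy/dt = G y."""
    species = ONE_STAGE_SPECIES if rates.kd is None else TWO_STAGE_SPECIES
    index = {name: pos for pos, name in enumerate(species)}
    G = np.zeros((len(species), len(species)))
    ki, kj = rates.ki, rates.kj

    def edge(src: str, rate: float, *targets: str) -> None:
        G[index[src], index[src]] -= rate
        for dst in targets:
            G[index[dst], index[src]] += rate

    if rates.kd is None:
        edge("masked", rates.kdf, "ABC")
    else:
        edge("masked", rates.kdf, "core")
        edge("core", rates.kd, "ABC")
    # chain scission yields both flanking fragments
    edge("ABC", ki, "A", "BC")
    edge("ABC", kj, "AB", "C")
    edge("AB", ki, "A", "B")
    edge("BC", kj, "B", "C")
    return G, species


def _expm_concentrations(rates: RateSet, times: np.ndarray) -> dict[str, np.ndarray]:
    G, species = _generator(rates)
    y0 = np.zeros(len(species))
    y0[0] = 1.0
    out = {name: np.empty_like(times) for name in species}
    for pos, t in enumerate(times):
        y = expm(G * t) @ y0
        for name, value in zip(species, y):
            out[name][pos] = value
    return out


# -- closed forms --------------------------------------------------------


def _one_stage_values(rates: RateSet, t: np.ndarray) -> dict[str, np.ndarray]:
    kdf, ki, kj = rates.kdf, rates.ki, rates.kj
    K = ki + kj
    e_df, e_K = np.exp(-kdf * t), np.exp(-K * t)
    e_i, e_j = np.exp(-ki * t), np.exp(-kj * t)
    masked = e_df
    ABC = kdf / (K - kdf) * (e_df - e_K)
    AB = (
        kdf * kj / ((K - kdf) * (ki - kdf)) * e_df
        + kdf / (K - kdf) * e_K
        - kdf / (ki - kdf) * e_i
    )
    BC = (
        kdf * ki / ((K - kdf) * (kj - kdf)) * e_df
        + kdf / (K - kdf) * e_K
        - kdf / (kj - kdf) * e_j
    )
    A = 1 - ki / (ki - kdf) * e_df + kdf / (ki - kdf) * e_i
    C = 1 - kj / (kj - kdf) * e_df + kdf / (kj - kdf) * e_j
    B = 1 - masked - ABC - AB - BC
    return {"masked": masked, "ABC": ABC, "AB": AB, "BC": BC, "A": A, "B": B, "C": C}


def one_stage_concentrations(
    rates: RateSet, times
) -> dict[str, ConcentrationCurve]:
    """Concentration curves of all seven one-stage species on a time grid."""
    if rates.kd is not None:
        raise KineticsError("one-stage scheme takes a RateSet without kd")
    rates._require_hydrolyzable()
    t = _check_times(times)
    if is_degenerate(rates):
        values = _expm_concentrations(rates, t)
    else:
        values = _one_stage_values(rates, t)
    return {
        name: ConcentrationCurve(name, "time", t, values[name])
        for name in ONE_STAGE_SPECIES
    }


def two_stage_coefficients(rates: RateSet) -> dict[str, CoefficientSet]:
    """Exponential-sum coefficients of the six two-stage product species.

    Requires pairwise non-degenerate rates; near coincidences the curves
    must be evaluated through the matrix-exponential path instead.
    """
    if rates.kd is None:
        raise KineticsError("two-stage scheme requires kd")
    rates._require_hydrolyzable()
    if is_degenerate(rates):
        raise KineticsError(
            "degenerate rate set: coefficient algebra is singular; "
            "use two_stage_concentrations, which takes the limit path"
        )
    D, d, ki, kj = rates.kdf, rates.kd, rates.ki, rates.kj
    K = ki + kj
    decay = (0.0, D, K, d, ki, kj)

    # ABC: masked ->(D) core ->(d) ABC ->(K) cleaved
    abc1 = D * d / ((d - D) * (K - D))
    abc2 = D * d / ((K - d) * (K - D))
    abc3 = -D * d / ((d - D) * (K - d))
    ABC = (0.0, abc1, abc2, abc3, 0.0, 0.0)

    # AB: dAB/dt = kj*ABC - ki*AB, term-by-term integration
    ab1 = kj * abc1 / (ki - D)
    ab2 = kj * abc2 / (ki - K)
    ab3 = kj * abc3 / (ki - d)
    AB = (0.0, ab1, ab2, ab3, -(ab1 + ab2 + ab3), 0.0)

    bc1 = ki * abc1 / (kj - D)
    bc2 = ki * abc2 / (kj - K)
    bc3 = ki * abc3 / (kj - d)
    BC = (0.0, bc1, bc2, bc3, 0.0, -(bc1 + bc2 + bc3))

    # A tracks hydrolysis of bond i: three-step chain D -> d -> ki
    a1 = -d * ki / ((d - D) * (ki - D))
    a3 = -D * ki / ((D - d) * (ki - d))
    a4 = -D * d / ((D - ki) * (d - ki))
    A = (1.0, a1, 0.0, a3, a4, 0.0)

    c1 = -d * kj / ((d - D) * (kj - D))
    c3 = -D * kj / ((D - d) * (kj - d))
    c5 = -D * d / ((D - kj) * (d - kj))
    C = (1.0, c1, 0.0, c3, 0.0, c5)

    # B by block material balance: B = 1 - masked - core - ABC - AB - BC
    core1, core3 = D / (d - D), -D / (d - D)
    B = (
        1.0,
        -(1.0 + core1 + abc1 + ab1 + bc1),
        -(abc2 + ab2 + bc2),
        -(core3 + abc3 + ab3 + bc3),
        -AB[4],
        -BC[5],
    )

    return {
        name: CoefficientSet(name, coeffs, decay)
        for name, coeffs in (
            ("A", A), ("B", B), ("C", C), ("AB", AB), ("BC", BC), ("ABC", ABC),
        )
    }


def two_stage_concentrations(
    rates: RateSet, times
) -> dict[str, ConcentrationCurve]:
    """Concentration curves of all eight two-stage species on a time grid."""
    if rates.kd is None:
        raise KineticsError("two-stage scheme requires kd")
    rates._require_hydrolyzable()
    t = _check_times(times)
    if is_degenerate(rates):
        values = _expm_concentrations(rates, t)
    else:
        D, d = rates.kdf, rates.kd
        values = {
            "masked": np.exp(-D * t),
            "core": D / (d - D) * (np.exp(-D * t) - np.exp(-d * t)),
        }
        for name, coeff in two_stage_coefficients(rates).items():
            values[name] = coeff.evaluate(t)
    return {
        name: ConcentrationCurve(name, "time", t, values[name])
        for name in TWO_STAGE_SPECIES
    }


def concentration_functions(rates: RateSet):
    """Map species -> callable(times) for the scheme the rates select.

    Thin functional view over the closed forms, used to re-express curves
    on a degree-of-hydrolysis grid without interpolation.
    """
    species = ONE_STAGE_SPECIES if rates.kd is None else TWO_STAGE_SPECIES
    evaluate = (
        one_stage_concentrations if rates.kd is None else two_stage_concentrations
    )

    def make(name: str):
        return lambda times: evaluate(rates, times)[name].values

    return {name: make(name) for name in species}


# -- per-bond hydrolysis -------------------------------------------------


def _chain_cut_fraction(chain_rates: tuple[float, ...], t: np.ndarray) -> np.ndarray:
    """Absorbed fraction of a first-order series chain (Bateman solution)."""
    rates = np.asarray(chain_rates, dtype=float)
    n = rates.size
    out = np.ones_like(t)
    for a in range(n):
        num = np.prod(np.delete(rates, a))
        den = np.prod(np.delete(rates, a) - rates[a])
        out -= num / den * np.exp(-rates[a] * t)
    return out


def _chain_cut_expm(chain_rates: tuple[float, ...], t: np.ndarray) -> np.ndarray:
    n = len(chain_rates)
    G = np.zeros((n + 1, n + 1))
    for a, rate in enumerate(chain_rates):
        G[a, a] = -rate
        G[a + 1, a] = rate
    y0 = np.zeros(n + 1)
    y0[0] = 1.0
    return np.array([(expm(G * ti) @ y0)[-1] for ti in t])


def bond_hydrolysis_fraction(
    mechanism: str,
    kdf: float,
    kj: float,
    t,
    kd: float | None = None,
) -> np.ndarray:
    """Fraction of one enzyme-specific bond hydrolyzed by time ``t`` (min).

    One-stage: the demask-then-cleave solution
    ``N(t)/N0 = 1 - kj e^(-kdf t)/(kj - kdf) + kdf e^(-kj t)/(kj - kdf)``,
    with the analytic limit ``1 - e^(-k t)(1 + k t)`` at ``kj = kdf``.
    Two-stage: the series chain ``masked -> core -> demasked -> cut`` with
    rates ``(kdf, kd, kj)``.  Monotone, 0 at t = 0, tending to 1.
    """
    t = _check_times(t)
    if kdf <= 0 or kj <= 0:
        raise KineticsError("kdf and kj must be > 0")
    if mechanism == "one_stage":
        if _is_close(kj, kdf):
            k = 0.5 * (kj + kdf)
            return 1 - np.exp(-k * t) * (1 + k * t)
        return (
            1
            - kj * np.exp(-kdf * t) / (kj - kdf)
            + kdf * np.exp(-kj * t) / (kj - kdf)
        )
    if mechanism == "two_stage":
        if kd is None or kd <= 0:
            raise KineticsError("two-stage bond fraction requires kd > 0")
        chain = (kdf, kd, kj)
        if _is_close(kj, kdf) or _is_close(kj, kd) or _is_close(kdf, kd):
            return _chain_cut_expm(chain, t)
        return _chain_cut_fraction(chain, t)
    raise KineticsError(f"unknown mechanism {mechanism!r}")
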