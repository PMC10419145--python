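"""Brute-force numeric integration of the release networks.

Independent oracle for the closed forms in :mod:`pepdemask.kinetics`: the
same first-order networks are built explicitly as reaction lists and
integrated with a stiff-safe ODE solver at tight tolerances.  Not meant for
production simulation — its only job is to disagree with the closed forms
when they are wrong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import (
    ConcentrationCurve,
    KineticsError,
    ONE_STAGE_SPECIES,
    RateSet,
    TWO_STAGE_SPECIES,
)


class OracleError(RuntimeError):
    """Raised when the integrator fails to converge."""


@dataclass(frozen=True)
class ReactionNetwork:
    """First-order transitions over labelled pools.

    Each transition ``(source, targets, rate)`` drains the source pool and
    feeds every target pool; a chain scission of a fragment X-Y lists both
    flanking fragments as targets, which conserves block mass by
    construction.
    """

    labels: tuple[str, ...]
    transitions: tuple[tuple[str, tuple[str, ...], float], ...]

    def __post_init__(self) -> None:
        known = set(self.labels)
        for source, targets, rate in self.transitions:
            if rate < 0:
                raise KineticsError(f"negative rate on {source} -> {targets}")
            if source not in known or not set(targets) <= known:
                raise KineticsError(f"unknown pool in {source} -> {targets}")

    def generator(self) -> np.ndarray:
        index = {name: pos for pos, name in enumerate(self.labels)}
        G = np.zeros((len(self.labels),) * 2)
        for source, targets, rate in self.transitions:
            G[index[source], index[source]] -= rate
            for target in targets:
                G[index[target], index[source]] += rate
        return G


def build_network(mechanism: str, rates: RateSet) -> ReactionNetwork:
    """The one- or two-stage release network for one trimeric block."""
    ki, kj = rates.ki, rates.kj
    scission = (
        ("ABC", ("A", "BC"), ki),
        ("ABC", ("AB", "C"), kj),
        ("AB", ("A", "B"), ki),
        ("BC", ("B", "C"), kj),
    )
    if mechanism == "one_stage":
        return ReactionNetwork(
            labels=ONE_STAGE_SPECIES,
            transitions=(("masked", ("ABC",), rates.kdf),) + scission,
        )
    if mechanism == "two_stage":
        if rates.kd is None:
            raise KineticsError("two-stage network requires kd")
        return ReactionNetwork(
            labels=TWO_STAGE_SPECIES,
            transitions=(
                ("masked", ("core",), rates.kdf),
                ("core", ("ABC",), rates.kd),
            )
            + scission,
        )
    raise KineticsError(f"unknown mechanism {mechanism!r}")


def integrate(network: ReactionNetwork, times) -> dict[str, ConcentrationCurve]:
    """Integrate from the all-masked initial state on the given time grid."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0) or (t.size > 1 and not np.all(np.diff(t) > 0)):
        raise KineticsError("times must be non-negative and increasing")
    G = network.generator()
    y0 = np.zeros(len(network.labels))
    y0[0] = 1.0
    t_end = float(t[-1]) if t[-1] > 0 else 1.0
    solution = solve_ivp(
        lambda _, y: G @ y,
        (0.0, t_end),
        y0,
        t_eval=t,
        method="LSODA",
        rtol=1e-11,
        atol=1e-13,
        jac=lambda _, y: G,
    )
    if not solution.success:
        raise OracleError(f"ODE solver failed: {solution.message}")
    return {
        name: ConcentrationCurve(name, "time", t, solution.y[pos])
        for pos, name in enumerate(network.labels)
    }
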