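"""Estimation of hydrolysis rate constants from bond-disappearance curves.

A bond's hydrolyzed fraction under one-stage demasking follows
``N(t)/N0 = 1 - kj e^(-kdf t)/(kj - kdf) + kdf e^(-kj t)/(kj - kdf)``;
fitting this with the demasking constant ``kdf`` held fixed yields the
bond's hydrolysis rate constant ``k_j`` and, against a reference bond, the
relative constants tabulated for the substrate map.  Curves shaped by
two-stage demasking cannot be fit with the one-stage form; an optional
mode fits the three-step series chain instead, which needs denser sampling
to be well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .kinetics import KineticsError, bond_hydrolysis_fraction
from .substrate import KD_DEFAULT, KDF_DEFAULT


class FittingError(ValueError):
    """Raised for unusable kinetic data."""


@dataclass(frozen=True)
class BondKineticsData:
    """Hydrolyzed-fraction samples for one bond over time."""

    label: str
    times: np.ndarray
    values: np.ndarray
    n0: float = 1.0
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise FittingError(f"{self.label}: times/values must match")
        if np.any(t < 0) or (t.size > 1 and np.any(np.diff(t) <= 0)):
            raise FittingError(f"{self.label}: times must be non-negative, increasing")
        if np.any(v < -1e-9) or np.any(v > self.n0 * (1 + 1e-9)):
            raise FittingError(f"{self.label}: fractions must lie in [0, n0]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RateEstimate:
    """A fitted hydrolysis rate constant with its diagnostics."""

    label: str
    k_hat: float
    stderr: float
    residual_norm: float
    converged: bool
    n0_hat: float = 1.0
    kdf_hat: float | None = None


def fit_kj(
    data: BondKineticsData,
    kdf: float = KDF_DEFAULT,
    *,
    mechanism: str = "one_stage",
    kd: float = KD_DEFAULT,
    estimate_n0: bool = False,
    joint_kdf: bool = False,
) -> RateEstimate:
    """Least-squares estimate of a bond's hydrolysis rate constant.

    ``kdf`` is held fixed by default; ``joint_kdf=True`` co-estimates it.
    ``estimate_n0=True`` co-estimates the amplitude, making the fit
    invariant to uniform rescaling of the concentrations.  The model is
    evaluated through :func:`bond_hydrolysis_fraction`, whose analytic
    limit keeps the objective smooth across the degenerate point
    ``k_j = k_df``.
    """
    if len(data.times) < 4:
        raise FittingError(f"{data.label}: need >= 4 time points")
    if float(np.max(np.abs(data.values))) < 1e-12:
        raise FittingError(f"{data.label}: all-zero data, nothing to fit")
    if mechanism not in ("one_stage", "two_stage"):
        raise FittingError(f"unknown mechanism {mechanism!r}")
    kd_arg = kd if mechanism == "two_stage" else None

    names = ["kj"]
    if joint_kdf:
        names.append("kdf")
    if estimate_n0:
        names.append("n0")

    def model(t, *theta):
        params = dict(zip(names, theta))
        frac = bond_hydrolysis_fraction(
            mechanism, params.get("kdf", kdf), params["kj"], t, kd=kd_arg
        )
        return params.get("n0", data.n0) * frac

    p0 = {"kj": kdf, "kdf": kdf, "n0": max(data.values.max(), 1e-6)}
    lower = {"kj": 1e-8, "kdf": 1e-8, "n0": 1e-12}
    converged = True
    try:
        popt, pcov = curve_fit(
            model,
            data.times,
            data.values,
            p0=[p0[name] for name in names],
            bounds=([lower[name] for name in names], [np.inf] * len(names)),
            maxfev=20000,
        )
        perr = np.sqrt(np.diag(pcov))
    except (RuntimeError, KineticsError):
        converged = False
        popt = np.array([p0[name] for name in names])
        perr = np.full(len(names), np.nan)

    params = dict(zip(names, popt))
    errors = dict(zip(names, perr))
    residual = float(np.linalg.norm(data.values - model(data.times, *popt)))
    return RateEstimate(
        label=data.label,
        k_hat=float(params["kj"]),
        stderr=float(errors["kj"]),
        residual_norm=residual,
        converged=converged,
        n0_hat=float(params.get("n0", data.n0)),
        kdf_hat=float(params["kdf"]) if joint_kdf else None,
    )


def relative_rates(
    estimates: dict[str, RateEstimate], reference: str
) -> dict[str, float]:
    """Rate constants relative to a reference bond, k_rel = k / k_ref."""
    if reference not in estimates:
        raise FittingError(f"reference bond {reference!r} missing from estimates")
    k_ref = estimates[reference].k_hat
    if k_ref <= 0:
        raise FittingError(f"reference bond {reference!r} has non-positive k")
    return {label: est.k_hat / k_ref for label, est in estimates.items()}
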