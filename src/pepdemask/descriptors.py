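"""Release descriptors for concentration-versus-degree curves.

Two scalar summaries compress a peptide's concentration curve sampled on
the degree-of-hydrolysis grid ``{0, 1.5, 3, 4.5, 6, 7.9} %``:

* for an intermediate peptide (ABC, AB, BC), the concentration-weighted
  mean release degree ``d_r = sum_i d_i C(d_i) / sum_i C(d_i)``;
* for a final peptide (A, B, C), the exponent ``n`` of the power fit
  ``C(d) = a (d / 7.9)^n``, with ``n < 1`` marking a convex (fast-release)
  curve and ``n > 1`` a concave (lagged-release) one.

The power fit is nonlinear least squares on the untransformed values with
``a`` free, because the grid includes ``d = 0`` (model value 0), which a
log transform cannot accommodate.  A log-linear alternative with ``a``
pinned to the last grid point is provided for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: the six-point degree grid (%) on which descriptors are evaluated
DEGREE_GRID = (0.0, 1.5, 3.0, 4.5, 6.0, 7.9)


class DescriptorError(ValueError):
    """Raised for degenerate descriptor inputs."""


@dataclass(frozen=True)
class ReleaseDescriptor:
    """Weighted mean release degree of an intermediate peptide."""

    label: str
    d_r: float


@dataclass(frozen=True)
class PowerFitResult:
    """Fitted ``C = a (d/7.9)^n`` for a final peptide."""

    label: str
    a: float
    n: float
    residual_norm: float
    warning: str | None = None


def release_degree(
    concentrations, d_grid=DEGREE_GRID, *, label: str = ""
) -> ReleaseDescriptor:
    """Concentration-weighted mean degree of hydrolysis of a release curve."""
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(d_grid, dtype=float)
    if c.shape != d.shape:
        raise DescriptorError("concentrations and grid must have equal length")
    if np.any(c < 0):
        raise DescriptorError("concentrations must be >= 0")
    total = c.sum()
    if total <= 0:
        raise DescriptorError("all-zero concentrations: d_r is undefined")
    return ReleaseDescriptor(label=label, d_r=float((d * c).sum() / total))


def power_exponent(
    concentrations, d_grid=DEGREE_GRID, *, label: str = ""
) -> PowerFitResult:
    """Least-squares fit of ``C = a (d/7.9)^n`` with both parameters free."""
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(d_grid, dtype=float)
    if c.shape != d.shape:
        raise DescriptorError("concentrations and grid must have equal length")
    if np.count_nonzero(c > 0) < 3:
        raise DescriptorError("need at least three positive concentrations")
    note = None
    if np.any(np.diff(c) < -1e-12):
        note = "non-monotone input: final-product curves should be non-decreasing"

    def model(dd, a, n):
        return a * (dd / 7.9) ** n

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        popt, _ = curve_fit(
            model,
            d,
            c,
            p0=[max(c.max(), 1e-6), 1.0],
            bounds=([1e-12, 1e-6], [np.inf, np.inf]),
            maxfev=20000,
        )
    a, n = float(popt[0]), float(popt[1])
    residual = float(np.linalg.norm(c - model(d, a, n)))
    return PowerFitResult(label=label, a=a, n=n, residual_norm=residual, warning=note)


def power_exponent_loglinear(
    concentrations, d_grid=DEGREE_GRID, *, label: str = ""
) -> PowerFitResult:
    """Log-linear alternative fit with ``a`` pinned to the last grid value.

    Regresses ``log C`` on ``log(d/7.9)`` over the positive grid points with
    the intercept fixed at ``log C(d_last)``; used to report the sensitivity
    of ``n`` to the fitting convention.
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(d_grid, dtype=float)
    keep = (d > 0) & (c > 0)
    if keep.sum() < 3:
        raise DescriptorError("need at least three positive concentrations")
    a = float(c[-1])
    x = np.log(d[keep] / d[-1])
    y = np.log(c[keep] / a)
    # least squares through the origin: n = <x, y> / <x, x>
    denom = float(x @ x)
    n = float(x @ y) / denom if denom > 0 else 1.0
    residual = float(np.linalg.norm(c[keep] - a * (d[keep] / d[-1]) ** n))
    return PowerFitResult(label=label, a=a, n=n, residual_norm=residual)


@dataclass(frozen=True)
class ComparisonStats:
    """Summary of calculated-versus-experimental descriptor agreement."""

    mean_abs_diff: float
    n_pairs: int
    pooled_min: float
    pooled_max: float


def mean_abs_difference(calc, exp) -> ComparisonStats:
    """Mean |calculated - experimental| over labels present in both.

    ``calc`` and ``exp`` are mappings label -> value; pairs with a missing
    (None/NaN) experimental value are dropped, never imputed as zero.
    """
    pairs = []
    for key, value in dict(calc).items():
        other = dict(exp).get(key)
        if other is None or (isinstance(other, float) and np.isnan(other)):
            continue
        pairs.append((float(value), float(other)))
    if not pairs:
        raise DescriptorError("no overlapping labelled pairs to compare")
    arr = np.asarray(pairs)
    return ComparisonStats(
        mean_abs_diff=float(np.mean(np.abs(arr[:, 0] - arr[:, 1]))),
        n_pairs=len(pairs),
        pooled_min=float(arr.min()),
        pooled_max=float(arr.max()),
    )


@dataclass(frozen=True)
class ProportionalityStats:
    """Per-pair calculated/experimental ratios and their mean +/- sd."""

    mean_ratio: float
    sd_ratio: float
    ratios: tuple[float, ...]
    dropped: tuple[str, ...] = ()


def proportionality(calc, exp) -> ProportionalityStats:
    """Mean and standard deviation of per-label calc/exp ratios.

    Defined as the mean of per-peptide ratios (not a regression slope);
    labels with a zero or missing experimental value are dropped with a
    warning.
    """
    ratios, dropped = [], []
    for key, value in dict(calc).items():
        other = dict(exp).get(key)
        if (
            other is None
            or (isinstance(other, float) and np.isnan(other))
            or float(other) == 0.0
        ):
            dropped.append(str(key))
            continue
        ratios.append(float(value) / float(other))
    if dropped:
        warnings.warn(f"dropped pairs with zero/missing experimental value: {dropped}")
    if not ratios:
        raise DescriptorError("no usable pairs for the proportionality ratio")
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return ProportionalityStats(
        mean_ratio=float(arr.mean()),
        sd_ratio=sd,
        ratios=tuple(ratios),
        dropped=tuple(dropped),
    )
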