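"""Polychromatic intensities, projections, and spectral moments.

For a normalized source i0(E) and sample LAC mu(E), the transmitted
intensity after a path of length s is

    I(s) = int i0(E) exp(-mu(E) s) dE,        I(0) = 1,

and the measured projection is p(s) = -ln I(s).  Beam hardening makes p
nonlinear in s; the package models it as a power series
h(s) = sum_{n=1..N} C_n s^n whose coefficients follow from the
attenuation-weighted spectral moments

    M_n(s) = int i0(E) mu(E)^n exp(-mu(E) s) dE,   mu_n(s) = M_n(s)/I(s),

through nu_n = (-1)^n mu_n(0)/n! and the recurrence

    C_{n+1} = -nu_{n+1} - sum_{m=1..n} nu_{n-m+1} (m/(n+1)) C_m,

with C_1 = mu_1(0) (the effective LAC at zero thickness).

All energy integrals share one quadrature rule: trapezoid on the union of
the two grids, split at every K edge with one-sided limits on each side.
Moment integrands are evaluated as exp(n ln mu - mu s + ln i0) so that
orders up to N = 100 stay finite even where mu^n alone would overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln

from .spectra import EnergySpectrum, SpectrumError

__all__ = [
    "MomentError",
    "MomentSet",
    "ProjectionSeries",
    "intensity",
    "projection_p",
    "moment_Mn",
    "normalized_moments",
    "nu_coefficients",
    "series_coefficients",
    "h_series",
    "intensity_series_check",
    "SeriesIntensity",
]


class MomentError(ValueError):
    """Raised for invalid moment/projection arguments or numeric failure."""


@dataclass(frozen=True, eq=False)
class MomentSet:
    """Normalized spectral moments mu_n(0) for n = 0..N (units 1/cm^n)."""

    order_N: int
    mu_n0: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu_n0, dtype=float)).copy()
        if self.order_N < 1:
            raise MomentError("order N must be >= 1")
        if mu.shape != (self.order_N + 1,):
            raise MomentError("mu_n0 must have length N+1 (n = 0..N)")
        if not np.all(np.isfinite(mu)):
            raise MomentError("moments must be finite")
        if mu[0] != 1.0:
            raise MomentError("mu_0(0) must be exactly 1 (normalized source)")
        mu.setflags(write=False)
        object.__setattr__(self, "mu_n0", mu)


@dataclass(frozen=True, eq=False)
class ProjectionSeries:
    """Power-series projection h(s) = sum C_n s^n on 0 <= s <= 2R."""

    order_N: int
    coeffs_C: np.ndarray  # C_1..C_N, units 1/cm^n
    radius_R_cm: float

    def __post_init__(self) -> None:
        C = np.atleast_1d(np.asarray(self.coeffs_C, dtype=float)).copy()
        if C.shape != (self.order_N,):
            raise MomentError("coeffs_C must have length N (C_1..C_N)")
        if not np.all(np.isfinite(C)):
            raise MomentError("series coefficients must be finite")
        if not (self.radius_R_cm > 0):
            raise MomentError("radius must be positive")
        C.setflags(write=False)
        object.__setattr__(self, "coeffs_C", C)

    def __call__(self, s_cm):
        return h_series(self, s_cm)


# ---------------------------------------------------------------------------
# shared quadrature tables


@lru_cache(maxsize=64)
def _pair_segments(source: EnergySpectrum, lac: EnergySpectrum):
    """Per-segment (x, i0, mu, ln_i0, ln_mu) tables on the union grid.

    Segments are delimited by the K edges of either spectrum; the value at
    a segment's upper bound is the left (pre-edge) limit, at its lower
    bound the right (post-edge) limit, so no trapezoid spans a jump.
    """
    lo = max(source.energies_keV[0], lac.energies_keV[0])
    hi = min(source.energies_keV[-1], lac.energies_keV[-1])
    if hi <= lo:
        raise MomentError("source and LAC energy grids do not overlap")
    edges = sorted(
        {e for e in source.edge_energies_keV + lac.edge_energies_keV if lo < e < hi}
    )
    xs_all = np.unique(
        np.concatenate(
            [source.energies_keV, lac.energies_keV, np.asarray([lo, hi] + edges)]
        )
    )
    xs_all = xs_all[(xs_all >= lo) & (xs_all <= hi)]
    bounds = [lo, *edges, hi]
    segs = []
    with np.errstate(divide="ignore"):
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            m = (xs_all >= a) & (xs_all <= b)
            x = xs_all[m]
            i0 = np.atleast_1d(source(x))
            mu = np.atleast_1d(lac(x))
            if i < len(bounds) - 2:  # b is an edge: use the pre-edge limit
                i0[-1] = source(b, side="left")
                mu[-1] = lac(b, side="left")
            segs.append((x, i0, mu, np.log(i0), np.log(mu)))
    return tuple(segs)


def _source_norm(segs) -> float:
    return float(sum(np.trapezoid(i0, x) for x, i0, *_ in segs))


def intensity(source: EnergySpectrum, lac: EnergySpectrum, s_cm):
    """Transmitted intensity fraction I(s)/I(0) after path length s (cm)."""
    s = np.asarray(s_cm, dtype=float)
    scalar = s.ndim == 0
    sv = np.atleast_1d(s)
    if np.any(sv < 0):
        raise MomentError("path length s must be nonnegative")
    segs = _pair_segments(source, lac)
    I = np.zeros_like(sv)
    for x, i0, mu, *_ in segs:
        I += np.trapezoid(i0[None, :] * np.exp(-mu[None, :] * sv[:, None]), x, axis=1)
    I /= _source_norm(segs)
    return float(I[0]) if scalar else I


def projection_p(source: EnergySpectrum, lac: EnergySpectrum, s_cm):
    """Projection p(s) = -ln(I(s)/I(0)); Beer's law made polychromatic."""
    I = intensity(source, lac, s_cm)
    if np.any(np.asarray(I) <= 0):
        raise MomentError(
            "intensity underflowed to zero; reduce the path length or use a "
            "higher-precision quadrature grid"
        )
    return -np.log(I)


def moment_Mn(source: EnergySpectrum, lac: EnergySpectrum, n: int, s_cm: float = 0.0):
    """Attenuation-weighted moment M_n(s) = int i0 mu^n exp(-mu s) dE."""
    if n < 0:
        raise MomentError("moment order n must be nonnegative")
    s = float(s_cm)
    if s < 0:
        raise MomentError("path length s must be nonnegative")
    segs = _pair_segments(source, lac)
    total = 0.0
    for x, i0, mu, ln_i0, ln_mu in segs:
        if n == 0:
            integrand = i0 * np.exp(-mu * s)
        else:
            integrand = np.exp(n * ln_mu - mu * s + ln_i0)
        total += np.trapezoid(integrand, x)
    return total / _source_norm(segs)


def normalized_moments(source: EnergySpectrum, lac: EnergySpectrum, N: int) -> MomentSet:
    """mu_n(0) = M_n(0)/I(0) for n = 0..N; mu_0(0) == 1 by construction."""
    if N < 1:
        raise MomentError("order N must be >= 1")
    segs = _pair_segments(source, lac)
    norm = _source_norm(segs)
    n = np.arange(N + 1)
    mu_n0 = np.zeros(N + 1)
    for x, i0, mu, ln_i0, ln_mu in segs:
        integrand = np.exp(n[:, None] * ln_mu[None, :] + ln_i0[None, :])
        # n = 0 separately: 0 * (-inf) is NaN where i0 or mu vanishes
        integrand[0] = i0
        mu_n0 += np.trapezoid(integrand, x, axis=1)
    mu_n0 /= norm
    mu_n0[0] = 1.0
    return MomentSet(N, mu_n0)


def nu_coefficients(moments: MomentSet) -> np.ndarray:
    """nu_n = (-1)^n mu_n(0)/n! for n = 0..N, computed in log space.

    n! overflows past n ~ 170 while mu_n(0) grows geometrically, so the
    quotient is formed as exp(ln mu_n - ln n!) with the sign applied
    separately; N up to 100 (and beyond) stays representable.
    """
    n = np.arange(moments.order_N + 1)
    mu = moments.mu_n0
    sign = np.where(n % 2 == 0, 1.0, -1.0)
    with np.errstate(divide="ignore"):
        nu = sign * np.exp(np.log(np.abs(mu)) - gammaln(n + 1))
    nu = np.where(mu == 0.0, 0.0, nu)
    nu[0] = 1.0
    return nu


def series_coefficients(moments: MomentSet, radius_R_cm: float) -> ProjectionSeries:
    """Projection coefficients C_1..C_N from the moment recurrence.

    C_1 = mu_1(0); the higher coefficients encode the beam hardening.  The
    closed forms C_2 = (mu_1^2 - mu_2)/2 and
    C_3 = (2 mu_1^3 - 3 mu_1 mu_2 + mu_3)/6 are recovered exactly and are
    used as an independent oracle in the tests.
    """
    N = moments.order_N
    nu = nu_coefficients(moments)
    C = np.zeros(N + 1)
    for n in range(N):  # computes C_{n+1}
        acc = -nu[n + 1]
        for m in range(1, n + 1):
            acc -= nu[n - m + 1] * (m / (n + 1)) * C[m]
        C[n + 1] = acc
    return ProjectionSeries(N, C[1:], radius_R_cm)


def h_series(series: ProjectionSeries, s_cm):
    """Evaluate h(s) = sum C_n s^n on 0 <= s <= 2R.

    Warns when the truncated tail |C_N (2R)^N| exceeds 1e-6 of |h(2R)|,
    signalling a truncation-dominated value.
    """
    s = np.asarray(s_cm, dtype=float)
    scalar = s.ndim == 0
    sv = np.atleast_1d(s)
    two_R = 2.0 * series.radius_R_cm
    if np.any(sv < 0) or np.any(sv > two_R * (1 + 1e-12)):
        raise MomentError(f"s must lie in [0, 2R] = [0, {two_R}] cm")
    C = series.coeffs_C
    coeffs = np.concatenate(([0.0], C))  # h(0) = 0
    h = np.polynomial.polynomial.polyval(sv, coeffs)
    h_edge = float(np.polynomial.polynomial.polyval(two_R, coeffs))
    tail = abs(C[-1]) * two_R ** series.order_N
    if tail > 1e-6 * max(abs(h_edge), np.finfo(float).tiny):
        warnings.warn(
            "h(s) is truncation-dominated: the last retained term "
            f"|C_N (2R)^N| = {tail:.3g} is not negligible against h(2R); "
            "increase N",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(h[0]) if scalar else h


class SeriesIntensity(NamedTuple):
    value: float
    diverged: bool


def intensity_series_check(moments: MomentSet, s_cm: float) -> SeriesIntensity:
    """Partial sum sum_{n<=N} nu_n s^n, which converges to I(s)/I(0).

    ``diverged`` flags a growing last term at the cutoff (the partial sums
    are still outside their asymptotic regime at this s and N).
    """
    s = float(s_cm)
    if s < 0:
        raise MomentError("path length s must be nonnegative")
    nu = nu_coefficients(moments)
    terms = nu * s ** np.arange(moments.order_N + 1)
    diverged = bool(
        moments.order_N >= 1 and abs(terms[-1]) > abs(terms[-2]) and terms[-1] != 0.0
    )
    return SeriesIntensity(float(terms.sum()), diverged)
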