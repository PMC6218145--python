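"""Exact analytic cupping profile of a homogeneous cylindrical phantom.

Filtered backprojection of the power-series projection h(s) = sum C_n s^n
with an ideal ramp filter (infinite Nyquist wavenumber) yields a closed
form for the reconstructed LAC along the radius:

    f(r) = sum_{n=1..N} F_n (R^2 - r^2)^{(n-1)/2},    0 <= r < R,
    f(R) = C_1 / 2,

with

    F_n = 2^n Gamma(n/2 + 1) / (sqrt(pi) Gamma((n+1)/2)) * C_n.

F_1 = C_1, so a linear projection (monochromatic beam) gives a flat disk;
every higher C_n contributes an r-dependent (cupping) term.  The value at
the rim itself is the half-jump C_1/2 characteristic of a Fourier
reconstruction across a discontinuity, while the limit from inside is C_1.

The helper sequence G_n = 2 Gamma(n/2+1)/(sqrt(pi) Gamma((n+1)/2)) obeys
G_n = 2n / (pi G_{n-1}) with G_0 = 2/pi, and F_n = 2^{n-1} G_n C_n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .moments import ProjectionSeries

__all__ = [
    "CuppingProfile",
    "G_sequence",
    "profile_from_series",
    "evaluate_f",
    "cupping_magnitude",
    "to_hounsfield",
    "LAC_1000_HU",
]

#: reconstructed LAC corresponding to 1000 HU in the package's reporting rule
LAC_1000_HU = 0.48


@dataclass(frozen=True, eq=False)
class CuppingProfile:
    """Coefficients F_1..F_N of the analytic radial profile f(r).

    ``C1`` is retained separately: it is the rim limit of f and enters the
    half-jump value f(R) = C1/2.
    """

    order_N: int
    coeffs_F: np.ndarray
    radius_R_cm: float
    C1: float

    def __post_init__(self) -> None:
        F = np.atleast_1d(np.asarray(self.coeffs_F, dtype=float)).copy()
        if F.shape != (self.order_N,):
            raise ValueError("coeffs_F must have length N (F_1..F_N)")
        if not np.all(np.isfinite(F)):
            raise ValueError("profile coefficients must be finite")
        if not (self.radius_R_cm > 0):
            raise ValueError("radius must be positive")
        F.setflags(write=False)
        object.__setattr__(self, "coeffs_F", F)

    def __call__(self, r_cm):
        return evaluate_f(self, r_cm)

    @property
    def rim_value(self) -> float:
        """f(R) itself: the deliberate half-jump C_1/2, never interpolated."""
        return self.C1 / 2.0


def _gamma_ratio(n: np.ndarray) -> np.ndarray:
    """2^n Gamma(n/2+1) / (sqrt(pi) Gamma((n+1)/2)), in log space.

    Log-gamma keeps the ratio stable out to N = 100 and beyond.
    """
    n = np.asarray(n, dtype=float)
    return np.exp(
        n * np.log(2.0) + gammaln(n / 2.0 + 1.0) - gammaln((n + 1.0) / 2.0)
        - 0.5 * np.log(np.pi)
    )


def G_sequence(N: int) -> np.ndarray:
    """G_1..G_N via the recurrence G_n = 2n/(pi G_{n-1}), G_0 = 2/pi."""
    if N < 1:
        raise ValueError("N must be >= 1")
    out = np.empty(N)
    g = 2.0 / np.pi
    for n in range(1, N + 1):
        g = 2.0 * n / (np.pi * g)
        out[n - 1] = g
    return out


def profile_from_series(series: ProjectionSeries) -> CuppingProfile:
    """Convert projection coefficients C_n into profile coefficients F_n."""
    n = np.arange(1, series.order_N + 1)
    F = _gamma_ratio(n) * series.coeffs_C
    F[0] = series.coeffs_C[0]  # ratio(1) == 1 analytically; keep F_1 = C_1 exact
    return CuppingProfile(series.order_N, F, series.radius_R_cm, float(series.coeffs_C[0]))


def evaluate_f(profile: CuppingProfile, r_cm):
    """Reconstructed LAC f(r) (1/cm) at radii 0 <= r <= R.

    (R^2 - r^2)^{(n-1)/2} is formed as exp(((n-1)/2) ln(R^2 - r^2)) with the
    r = R case short-circuited to the half-jump C_1/2, avoiding the 0^0
    ambiguity of the n = 1 term at the rim.  Outside the sample the analytic
    form does not apply and the call raises.
    """
    r = np.asarray(r_cm, dtype=float)
    scalar = r.ndim == 0
    rv = np.atleast_1d(r)
    R = profile.radius_R_cm
    if np.any(rv < 0) or np.any(rv > R):
        raise ValueError(f"r must lie within the sample, 0 <= r <= R = {R} cm")
    out = np.empty_like(rv)
    at_rim = rv == R
    out[at_rim] = profile.rim_value
    inside = ~at_rim
    if inside.any():
        u = np.log(R * R - rv[inside] ** 2)
        half_pow = (np.arange(1, profile.order_N + 1) - 1) / 2.0
        terms = profile.coeffs_F[:, None] * np.exp(half_pow[:, None] * u[None, :])
        out[inside] = terms.sum(axis=0)
    return float(out[0]) if scalar else out


def cupping_magnitude(profile: CuppingProfile) -> float:
    """Center-to-rim depression C_1 - f(0) (1/cm); zero without hardening."""
    return profile.C1 - evaluate_f(profile, 0.0)


def to_hounsfield(f_per_cm, lac_1000_hu: float = LAC_1000_HU):
    """Report a reconstructed LAC on the clinical scale, HU = 1000 f / 0.48."""
    return 1000.0 * np.asarray(f_per_cm, dtype=float) / lac_1000_hu
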