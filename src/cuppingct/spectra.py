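"""Energy spectra, phantom and scanner descriptions, and synthetic generators.

Units are fixed package-wide: photon energy in keV, lengths in cm, linear
attenuation coefficients (LAC) in 1/cm, mass attenuation coefficients in
cm^2/g.  Source spectra are per-keV densities; a "normalized" source
integrates to one so that the unattenuated intensity is I(0) = 1.

Spectra are tabulated on a strictly increasing energy grid and treated as
piecewise-linear functions.  K absorption edges are first-class: an
:class:`EnergySpectrum` records its edge energies, interpolation never
crosses an edge (one-sided limits on each side), and every quadrature is
split at each edge so the discontinuity never spans a trapezoid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpectrumError",
    "EnergySpectrum",
    "CylinderPhantom",
    "ScannerGeometry",
    "normalize_source",
    "synth_source",
    "synth_lac",
    "mixture_lac",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "default_grid",
    "monochromatic_pair",
    "tube_source_100kv",
    "iodinated_water_lac",
]

#: electron rest energy, keV (Compton kinematics)
_MEC2_KEV = 511.0

#: reference energy (keV) at which photoelectric amplitudes are quoted
PE_REFERENCE_KEV = 30.0


class SpectrumError(ValueError):
    """Raised for physically or structurally invalid spectra."""


@dataclass(frozen=True, eq=False)
class EnergySpectrum:
    """Tabulated function of photon energy with optional K-edge markers.

    Parameters
    ----------
    energies_keV
        Strictly increasing grid of photon energies (keV), length >= 2.
    values
        Nonnegative samples: per-keV density for source spectra, 1/cm for
        LAC spectra, cm^2/g for mass-attenuation tables.
    edge_energies_keV
        Locations of discontinuities (K absorption edges).  Each must lie
        strictly inside the grid range.  At an edge the tabulated value is
        the post-edge (right) limit; the pre-edge limit is recovered by
        one-sided extrapolation of the segment below the edge.
    """

    energies_keV: np.ndarray
    values: np.ndarray
    edge_energies_keV: tuple = ()

    def __post_init__(self) -> None:
        E = np.atleast_1d(np.asarray(self.energies_keV, dtype=float)).copy()
        V = np.atleast_1d(np.asarray(self.values, dtype=float)).copy()
        if E.ndim != 1 or V.shape != E.shape:
            raise SpectrumError("energies and values must be 1-D arrays of equal length")
        if E.size < 2:
            raise SpectrumError("a spectrum needs at least two grid points")
        if not np.all(np.isfinite(E)) or not np.all(np.isfinite(V)):
            raise SpectrumError("non-finite entries in spectrum table")
        if not np.all(np.diff(E) > 0):
            raise SpectrumError("energies must be strictly increasing")
        if np.any(V < 0):
            raise SpectrumError("spectrum values must be nonnegative")
        edges = tuple(sorted(float(e) for e in self.edge_energies_keV))
        for e in edges:
            if not (E[0] < e < E[-1]):
                raise SpectrumError(
                    f"edge at {e} keV lies outside the open grid range "
                    f"({E[0]}, {E[-1]}) keV"
                )
        E.setflags(write=False)
        V.setflags(write=False)
        object.__setattr__(self, "energies_keV", E)
        object.__setattr__(self, "values", V)
        object.__setattr__(self, "edge_energies_keV", edges)

    # ---- piecewise-linear model with one-sided limits at edges ----

    @cached_property
    def _segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(x, y) tables per edge-delimited segment, with one-sided
        boundary values appended where an edge does not coincide with a
        grid point (or, on the left side of an edge, where the grid value
        carries the post-edge limit)."""
        E, V = self.energies_keV, self.values
        bounds = (float(E[0]), *self.edge_energies_keV, float(E[-1]))
        segs: list[tuple[np.ndarray, np.ndarray]] = []
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            right_is_edge = i < len(bounds) - 2
            if right_is_edge:
                m = (E >= a) & (E < b)
            else:
                m = (E >= a) & (E <= b)
            x, y = E[m], V[m]
            if x.size < 2:
                raise SpectrumError(
                    f"grid too coarse between {a} and {b} keV: each "
                    "edge-delimited segment needs at least two samples"
                )
            if x[0] > a:  # a is an edge with no grid point at it: back-extrapolate
                slope = (y[1] - y[0]) / (x[1] - x[0])
                y_a = max(y[0] + slope * (a - x[0]), 0.0)
                x = np.concatenate(([a], x))
                y = np.concatenate(([y_a], y))
            if x[-1] < b:  # b is an edge: append the pre-edge (left) limit
                slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
                y_b = max(y[-1] + slope * (b - x[-1]), 0.0)
                x = np.concatenate((x, [b]))
                y = np.concatenate((y, [y_b]))
            segs.append((x, y))
        return segs

    def __call__(self, energy_keV, side: str = "right"):
        """Interpolate at ``energy_keV`` (keV), never across an edge.

        ``side`` selects which limit is returned for a query exactly at an
        edge energy ("right", the default, is the post-edge value).
        """
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        E = np.asarray(energy_keV, dtype=float)
        scalar = E.ndim == 0
        Eq = np.atleast_1d(E)
        lo, hi = self.energies_keV[0], self.energies_keV[-1]
        if np.any(Eq < lo) or np.any(Eq > hi):
            raise SpectrumError(
                f"query energy outside tabulated range [{lo}, {hi}] keV"
            )
        out = np.empty_like(Eq)
        edges = np.asarray(self.edge_energies_keV)
        idx = np.searchsorted(edges, Eq, side=side)
        for k, (x, y) in enumerate(self._segments):
            m = idx == k
            if m.any():
                out[m] = np.interp(Eq[m], x, y)
        return float(out[0]) if scalar else out

    def integrate(self) -> float:
        """Trapezoidal integral over the grid, split at every edge."""
        return float(sum(np.trapezoid(y, x) for x, y in self._segments))

    def with_values(self, values) -> "EnergySpectrum":
        return EnergySpectrum(self.energies_keV, values, self.edge_energies_keV)


@dataclass(frozen=True)
class CylinderPhantom:
    """Homogeneous cylinder of radius ``radius_R_cm`` with LAC spectrum ``lac``."""

    radius_R_cm: float
    lac: EnergySpectrum

    def __post_init__(self) -> None:
        if not (self.radius_R_cm > 0):
            raise ValueError("phantom radius must be positive")


@dataclass(frozen=True)
class ScannerGeometry:
    """Parallel-beam scanner: detector pitch, counts, and image raster.

    ``n_angles`` projections are spread uniformly over the half rotation
    [0, pi); the reconstructed image is square with voxel size equal to the
    detector pitch, and the rotation center sits at the image center.
    """

    delta_cm: float = 0.01
    n_detectors: int = 512
    n_angles: int = 805
    image_size_vox: int = 512

    def __post_init__(self) -> None:
        if not (self.delta_cm > 0):
            raise ValueError("detector pitch must be positive")
        for name in ("n_detectors", "n_angles", "image_size_vox"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def nyquist_per_cm(self) -> float:
        """Band limit of the discrete reconstruction filters, 1/(2*delta)."""
        return 1.0 / (2.0 * self.delta_cm)

    @property
    def detector_positions_cm(self) -> np.ndarray:
        """Detector coordinates t, symmetric about the rotation axis."""
        n = self.n_detectors
        return (np.arange(n) - (n - 1) / 2.0) * self.delta_cm


# ---------------------------------------------------------------------------
# operations


def normalize_source(spec: EnergySpectrum) -> EnergySpectrum:
    """Rescale a source spectrum so its integral is one (I(0) = 1)."""
    total = spec.integrate()
    if not np.isfinite(total) or total <= 0:
        raise SpectrumError("cannot normalize a spectrum with nonpositive integral")
    if abs(total - 1.0) <= 4 * np.finfo(float).eps:
        return spec  # already normalized; keep bit-exact idempotence
    return spec.with_values(spec.values / total)


def default_grid(lo_keV: float = 10.0, hi_keV: float = 100.0, step_keV: float = 0.1) -> np.ndarray:
    """Uniform energy grid used by the synthetic generators."""
    n = int(round((hi_keV - lo_keV) / step_keV)) + 1
    return np.linspace(lo_keV, hi_keV, n)


def _klein_nishina_shape(E_keV: np.ndarray) -> np.ndarray:
    """Total Klein-Nishina cross-section, normalized to 1 at 60 keV."""

    def sigma(E):
        k = np.asarray(E, dtype=float) / _MEC2_KEV
        return (
            (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
            + np.log1p(2 * k) / (2 * k)
            - (1 + 3 * k) / (1 + 2 * k) ** 2
        )

    return sigma(E_keV) / sigma(60.0)


def synth_lac(
    photoelectric_amp: float,
    compton_amp: float,
    grid: np.ndarray,
    kedge_keV: float | None = None,
    kedge_jump: float = 1.0,
) -> EnergySpectrum:
    """Synthetic LAC (or mass-attenuation) spectrum.

    mu(E) = compton_amp * g(E) + photoelectric_amp * (30/E)^3 * J(E)

    where g is the Klein-Nishina shape (1 at 60 keV) and J(E) multiplies the
    photoelectric term by ``kedge_jump`` for E >= ``kedge_keV``.  The
    photoelectric amplitude is therefore the photoelectric value at 30 keV
    below the edge.  Monotone decreasing except for the single upward jump.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size < 2:
        raise SpectrumError("grid must contain at least two energies")
    if photoelectric_amp < 0 or compton_amp < 0:
        raise SpectrumError("amplitudes must be nonnegative")
    if photoelectric_amp == 0 and compton_amp == 0:
        raise SpectrumError("at least one amplitude must be positive")
    if kedge_jump < 1:
        raise SpectrumError("K-edge jump factor must be >= 1")
    pe = photoelectric_amp * (PE_REFERENCE_KEV / grid) ** 3
    edges: tuple = ()
    if kedge_keV is not None:
        if not (grid[0] < kedge_keV < grid[-1]):
            raise SpectrumError(
                f"K-edge at {kedge_keV} keV outside grid "
                f"({grid[0]}, {grid[-1]}) keV"
            )
        pe = np.where(grid >= kedge_keV, kedge_jump * pe, pe)
        if kedge_jump > 1:
            edges = (float(kedge_keV),)
    mu = compton_amp * _klein_nishina_shape(grid) + pe
    return EnergySpectrum(grid, mu, edges)


def synth_source(
    kvp_keV: float,
    grid: np.ndarray,
    filtration: Sequence[tuple[EnergySpectrum, float]] = (),
    n_lines: int = 0,
    line_rel_amp: float = 0.5,
    line_sigma_keV: float = 1.2,
) -> EnergySpectrum:
    """Filtered bremsstrahlung tube spectrum, normalized to unit integral.

    The continuum follows the thick-target (Kramers) law ~ max(kvp/E - 1, 0),
    attenuated by exp(-sum mu_f(E) d_f) for each ``(lac, thickness_cm)``
    filter.  ``n_lines`` Gaussian characteristic lines (tungsten-target K
    lines at 0.593 kvp and 0.672 kvp, then molybdenum-like L/K fractions)
    are added with peak amplitude ``line_rel_amp`` times the filtered
    continuum maximum.  The spectrum is identically zero above kvp.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size < 2:
        raise SpectrumError("empty or degenerate energy grid")
    if kvp_keV <= grid[0]:
        raise SpectrumError("tube voltage must exceed the lowest grid energy")
    cont = np.clip(kvp_keV / grid - 1.0, 0.0, None)
    for lac, thickness in filtration:
        cont = cont * np.exp(-lac(grid) * float(thickness))
    vals = cont.copy()
    if n_lines:
        fractions = (0.593, 0.672, 0.175, 0.196)
        amp = line_rel_amp * cont.max()
        placed = 0
        for frac in fractions:
            if placed >= n_lines:
                break
            e0 = frac * kvp_keV
            if grid[0] < e0 < min(kvp_keV, grid[-1]):
                vals = vals + amp * np.exp(-0.5 * ((grid - e0) / line_sigma_keV) ** 2)
                placed += 1
    vals = np.where(grid <= kvp_keV, vals, 0.0)
    return normalize_source(EnergySpectrum(grid, vals))


def mixture_lac(
    component_mass_atten_tables: Sequence[EnergySpectrum],
    mass_fractions: Sequence[float],
    density_g_cm3: float,
) -> EnergySpectrum:
    """LAC of a homogeneous mixture: mu(E) = rho * sum_i w_i (mu/rho)_i(E).

    Components are resampled (one-sided at edges) onto the union grid over
    their common energy range; all component edges are carried over.
    """
    comps = list(component_mass_atten_tables)
    w = np.asarray(mass_fractions, dtype=float)
    if len(comps) == 0 or w.shape != (len(comps),):
        raise SpectrumError("need one mass fraction per component table")
    if np.any(w < 0):
        raise SpectrumError("mass fractions must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise SpectrumError("mass fractions must sum to 1")
    if not (density_g_cm3 > 0):
        raise SpectrumError("density must be positive")
    lo = max(c.energies_keV[0] for c in comps)
    hi = min(c.energies_keV[-1] for c in comps)
    if hi <= lo:
        raise SpectrumError("component energy grids do not overlap")
    edges = sorted({e for c in comps for e in c.edge_energies_keV if lo < e < hi})
    xs = np.unique(np.concatenate([c.energies_keV for c in comps] + [np.asarray(edges)]))
    xs = xs[(xs >= lo) & (xs <= hi)]
    vals = density_g_cm3 * sum(wi * c(xs) for wi, c in zip(w, comps))
    return EnergySpectrum(xs, vals, tuple(edges))


# ---------------------------------------------------------------------------
# CSV persistence: header `energy_keV,value`, `#` comment lines carry metadata


def write_spectrum_csv(spec: EnergySpectrum, path, metadata: dict | None = None) -> None:
    meta = dict(metadata or {})
    if spec.edge_energies_keV:
        meta["edges_keV"] = ",".join(repr(e) for e in spec.edge_energies_keV)
    lines = [f"# {k}={v}" for k, v in meta.items()]
    lines.append("energy_keV,value")
    lines.extend(
        f"{float(e)!r},{float(v)!r}" for e, v in zip(spec.energies_keV, spec.values)
    )
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_csv(path, return_metadata: bool = False):
    """Read a two-column spectrum CSV; raises naming the offending row."""
    meta: dict[str, str] = {}
    energies: list[float] = []
    values: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols[:2] != ["energy_keV", "value"]:
                raise SpectrumError(
                    f"{path}: line {lineno}: expected header 'energy_keV,value'"
                )
            header_seen = True
            continue
        parts = line.split(",")
        try:
            e, v = float(parts[0]), float(parts[1])
        except (ValueError, IndexError) as exc:
            raise SpectrumError(f"{path}: line {lineno}: unparseable row {line!r}") from exc
        if energies and e <= energies[-1]:
            raise SpectrumError(
                f"{path}: line {lineno}: energy {e} keV is not greater than "
                f"the previous energy {energies[-1]} keV"
            )
        energies.append(e)
        values.append(v)
    if not header_seen:
        raise SpectrumError(f"{path}: missing 'energy_keV,value' header")
    edges: tuple = ()
    if "edges_keV" in meta:
        edges = tuple(float(tok) for tok in meta["edges_keV"].split(",") if tok.strip())
    spec = EnergySpectrum(np.asarray(energies), np.asarray(values), edges)
    return (spec, meta) if return_metadata else spec


# ---------------------------------------------------------------------------
# presets: the study conditions used throughout the tests and examples


def monochromatic_pair(
    energy_keV: float, mu_per_cm: float, half_width_keV: float = 10.0, step_keV: float = 0.1
) -> tuple[EnergySpectrum, EnergySpectrum]:
    """A narrow-line source and a flat LAC of value ``mu_per_cm``.

    The line is a triangle two grid steps wide (the package represents all
    spectra, including discrete lines, on a tabulated grid).  The LAC is
    constant across the grid, so Beer's law is exactly monochromatic:
    p(s) = mu * s regardless of the finite line width.
    """
    grid = default_grid(energy_keV - half_width_keV, energy_keV + half_width_keV, step_keV)
    center = np.argmin(np.abs(grid - energy_keV))
    vals = np.zeros_like(grid)
    vals[center] = 1.0
    source = normalize_source(EnergySpectrum(grid, vals))
    lac = EnergySpectrum(grid, np.full_like(grid, float(mu_per_cm)))
    return source, lac


def tube_source_100kv(grid: np.ndarray | None = None, n_lines: int = 2) -> EnergySpectrum:
    """100 kV tungsten-target-like tube spectrum behind Al- and Cu-like filters.

    The 0.1 cm aluminium-like and 0.01 cm copper-like filtrations push the
    spectrum mode to ~40-45 keV, emulating a metal-filtered micro-CT source.
    """
    if grid is None:
        grid = default_grid(10.0, 100.0, 0.1)
    al_like = synth_lac(3.0, 0.5, grid)
    cu_like = synth_lac(90.0, 3.0, grid)
    return synth_source(
        100.0, grid, filtration=((al_like, 0.1), (cu_like, 0.01)), n_lines=n_lines
    )


def iodinated_water_lac(grid: np.ndarray | None = None) -> EnergySpectrum:
    """LAC of a concentrated aqueous KI-like solution (iodine K-edge 33.2 keV).

    Amplitudes are set so the effective (source-weighted mean) LAC under
    :func:`tube_source_100kv` is ~0.96 1/cm, i.e. a strongly beam-hardening
    contrast phantom.
    """
    if grid is None:
        grid = default_grid(10.0, 100.0, 0.1)
    return synth_lac(0.57, 0.20, grid, kedge_keV=33.2, kedge_jump=5.5)
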