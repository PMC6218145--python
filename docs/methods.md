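# Methods

## Model and assumptions

The package treats the canonical beam-hardening geometry: a homogeneous
cylinder of radius R (cm) and LAC spectrum μ(E) (1/cm), illuminated by
parallel rays from a polychromatic source i₀(E) normalized to unit
integral, measured by a linear detector array of pitch δ (cm) over a 180°
rotation. Axisymmetry reduces the 2-D reconstruction to a radial profile
f(r). Scatter, detector energy response, bowtie filtration, fan/cone
geometry, and photon noise are all outside the model; the simulator is
deliberately noise-free so that the only discrepancy against the analytic
profile is the finite Nyquist wavenumber of the discrete filters.

The analytic chain is exact given two approximations: (i) the projection
p(s) = −ln I(s) is represented by its degree-N Maclaurin polynomial h(s),
whose coefficients Cₙ follow from the normalized spectral moments μₙ(0)
via νₙ = (−1)ⁿμₙ(0)/n! and the recurrence
Cₙ₊₁ = −νₙ₊₁ − Σₘ νₙ₋ₘ₊₁ (m/(n+1)) Cₘ; and (ii) ramp filtering with an
*infinite* band limit, which produces
f(r) = Σ Fₙ (R²−r²)^((n−1)/2) with Fₙ = 2ⁿΓ(n/2+1)/(√π Γ((n+1)/2))·Cₙ,
and the half-jump f(R) = C₁/2 typical of Fourier inversion across a
discontinuity. The chord-integration (Abel) identity — integrating f
along a chord at offset t returns h(2√(R²−t²)) term by term — is used as
an end-to-end test of the inversion without any Fourier machinery.

## Numerical choices

* **Quadrature.** All energy integrals use the trapezoid rule on the
  union of the source and LAC grids, split at every recorded K edge so a
  discontinuity never spans a trapezoid. Within a segment interpolation
  is linear and one-sided: the tabulated value *at* an edge is the
  post-edge limit, and the pre-edge limit is linearly extrapolated from
  the two samples below (O(step²) error, negligible on the default
  0.1 keV grid).
* **High orders.** μₙ(0) grows geometrically while n! overflows past
  n ≈ 170, so νₙ is formed as exp(ln μₙ − ln n!) with the sign applied
  separately, and the moment integrand as exp(n·ln μ − μs + ln i₀); both
  keep N = 100 (the default for production profiles) finite even where
  μⁿ alone would overflow. Gamma ratios for Fₙ use log-gamma. The helper
  recurrence Gₙ = 2n/(π Gₙ₋₁), G₀ = 2/π (with Fₙ = 2ⁿ⁻¹GₙCₙ) is kept as
  an independent cross-check of the log-gamma path.
* **Degenerate points.** (R²−r²)^((n−1)/2) is evaluated in log space with
  the r = R case short-circuited to C₁/2, avoiding the 0⁰ ambiguity of
  the n = 1 term at the rim. The half-jump is reported as a distinct
  field and never interpolated over.
* **Truncation guard.** `h_series` warns when |C_N (2R)^N| exceeds
  10⁻⁶·h(2R): the returned value is then truncation-dominated and N
  should be raised. The guard is advisory (a warning, not an error)
  because low-order evaluations are legitimate in convergence studies.
* **Series validity.** The partial sums of Σ νₙ sⁿ only enter their
  asymptotic regime once N exceeds roughly μ_max·s. For dilute aqueous
  phantoms μ_max·2R ≲ 30 and N = 100 is comfortable; at several mol/L of
  a heavy element the product outruns N = 100 and the truncated series is
  meaningless. The concentration solver therefore grows its root bracket
  geometrically from 0.05 mol/L so the first crossing of the target
  center value is found inside the convergent regime, and reports a
  bracket failure rather than a spurious root otherwise.

## Simulator conventions

Detectors sit at t = (m − (n_det−1)/2)·δ, symmetric about the rotation
axis; image voxels use the same convention with voxel size equal to δ and
the rotation center at the image center. The three reconstruction kernels
are the exact closed-form inverse transforms of the band-limited ramp
|z| ≤ 1/(2δ) under no taper (Ramachandran: 1/(4δ²) at lag 0, zero at even
lags, −1/(π²δ²m²) at odd lags), a sinc taper (Shepp: 2/(π²δ²(1−4m²))),
and a hanning taper (Chesler: the Ramachandran kernel smoothed by the
exact [¼, ½, ¼] lag stencil). Convolution runs in real space so the
Nyquist truncation is bit-reproducible; backprojection uses linear
interpolation in t and the angular weight π/n_angles. Radial profiles are
azimuthal averages in bins of one voxel width — legitimate under
axisymmetry and much quieter than a single ray. Profile comparisons split
at R − 5δ into interior and rim band, because the finite band limit
concentrates its error in the few voxels at the rim (strongest for the
heaviest low-pass, Chesler; weakest for Ramachandran).

The default geometry (δ = 0.01 cm, 512 detectors, 805 angles, 512²
image, R = 0.9 cm) is the package's reference configuration; everything
is overridable through `ScannerGeometry`.

## Synthetic study conditions

No public spectral data ship with the package; the generators emulate the
qualitative features that drive cupping, and real tables (e.g. NIST XCOM
exports) enter through the same CSV interface:

* **Source.** Kramers continuum ∝ max(kVp/E − 1, 0), attenuated by
  Al-like (0.1 cm) and Cu-like (0.01 cm) filters built from the same LAC
  model, plus optional Gaussian characteristic lines at tungsten-like
  energy fractions. The default 100 kV spectrum has its continuum mode
  near 39 keV. All spectra — including "monochromatic" lines, drawn as
  narrow triangles — share one tabulated representation.
* **LAC.** A Klein–Nishina-shaped Compton term plus a photoelectric
  E⁻³ term with a multiplicative K-edge jump (amplitudes quoted at
  30 keV). The KI-like default (photoelectric 0.57, Compton 0.20 1/cm,
  edge 33.2 keV, jump 5.5) was set so the source-weighted mean LAC is
  μ₁(0) ≈ 0.956 1/cm — a concentrated iodinated phantom with C₂/C₁ ≈
  −0.15, i.e. strong but realistic hardening.
* **Mixtures.** Solution LACs use ρ·Σ wᵢ(μ/ρ)ᵢ with a volume-additive
  bulk density (dissolved mass at the element's solid density, water
  filling the remainder of a liter). This is a stated substitute for
  empirical solution-density fits, so solved concentrations carry that
  model's uncertainty even when real attenuation tables are supplied.

What passing tests show — and do not show. The simulator validates the
analytic chain under its own assumptions; agreement there says nothing
about scatter, detector response, or noise in real scanners. Likewise the
contrast-agent scan demonstrates the *mechanism* (a K edge near the
source mode flattens the effective μ(E) and minimizes cupping at fixed
center value); absolute C₁ values for real agents require the user's
measured tube spectrum and element tables.

## Design notes

* The Cₙ recurrence is the single production code path; the explicit
  C₁–C₃ closed forms exist only as test oracles.
* The contrast figure of merit is C₁ − f(0) with the center fixed at
  0.48 1/cm (≈1000 HU under the package's reporting rule
  HU = 1000·f/0.48); the solver tolerance is 10⁻⁴ 1/cm. Brent
  root-bracketing was chosen over Newton because f(0) versus
  concentration inherits curvature from the K edge.
* In the synthetic element family the cupping minimum sits a few keV
  *above* the continuum mode (47 vs 39 keV at 100 kV) because the
  spectrum carries substantial weight above its mode; the tests assert
  the U-shape and near-mode minimum rather than a literal
  nearest-to-mode rule.
* Problem sizes: analytic chains run at N = 100; reconstructions at the
  full 512²/805-angle reference geometry (seconds each); unit tests use
  a 128²/201-angle scanner where full resolution adds nothing.

## Known limitations

* Projections with I(s) underflowing double precision (μ·s ≳ 700) raise
  instead of returning −log(0).
* The trapezoid rule is second-order; spectra with structure finer than
  the grid (real characteristic lines) need a correspondingly fine grid.
* The rim half-jump is a property of the ideal-ramp inversion, not of
  any finite-Nyquist reconstruction; measured rim voxels should be
  compared against the simulator, not the analytic f(R).
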