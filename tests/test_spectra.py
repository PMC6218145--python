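import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuppingct import (
    EnergySpectrum,
    ScannerGeometry,
    SpectrumError,
    default_grid,
    mixture_lac,
    normalize_source,
    read_spectrum_csv,
    synth_lac,
    synth_source,
    write_spectrum_csv,
)


class TestEnergySpectrum:
    def test_invariants_enforced(self):
        with pytest.raises(SpectrumError):
            EnergySpectrum([10.0], [1.0])  # fewer than two points
        with pytest.raises(SpectrumError):
            EnergySpectrum([10.0, 10.0, 20.0], [1.0, 1.0, 1.0])  # not increasing
        with pytest.raises(SpectrumError):
            EnergySpectrum([10.0, 20.0], [1.0, -0.5])  # negative value
        with pytest.raises(SpectrumError):
            EnergySpectrum([10.0, 20.0, 30.0], [1.0, 1.0, 1.0], (40.0,))  # edge outside

    def test_edge_split_integral_is_exact_for_step(self):
        # piecewise-constant with a recorded edge: the jump never spans a trapezoid
        grid = np.linspace(10.0, 90.0, 17)  # step 5, edge on a grid point
        vals = np.where(grid < 50.0, 1.0, 3.0)
        spec = EnergySpectrum(grid, vals, (50.0,))
        assert spec.integrate() == pytest.approx(1.0 * 40 + 3.0 * 40, abs=1e-12)

    def test_one_sided_interpolation_at_edge(self):
        grid = np.linspace(10.0, 90.0, 17)
        vals = np.where(grid < 50.0, 1.0, 3.0)
        spec = EnergySpectrum(grid, vals, (50.0,))
        assert spec(50.0) == pytest.approx(3.0)
        assert spec(50.0, side="left") == pytest.approx(1.0)
        assert spec(49.0) == pytest.approx(1.0)

    def test_quadrature_converges_at_second_order(self):
        # halving the step cuts the trapezoid error ~4x for an integrand
        # with nonvanishing endpoint slopes
        exact = 20.0 * (np.exp(-1.0) - np.exp(-4.0))
        errs = []
        for k in (6, 7, 8):
            grid = np.linspace(20.0, 80.0, 2**k + 1)
            errs.append(
                abs(EnergySpectrum(grid, np.exp(-grid / 20.0)).integrate() - exact)
            )
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)

    def test_quadrature_resolves_gaussian_line(self):
        # a narrow line integrates to its analytic area once the grid resolves it
        exact = np.sqrt(2 * np.pi) * 2.0
        grid = np.linspace(20.0, 80.0, 2**10 + 1)
        vals = np.exp(-0.5 * ((grid - 50.0) / 2.0) ** 2)
        assert EnergySpectrum(grid, vals).integrate() == pytest.approx(exact, rel=1e-10)


class TestNormalizeSource:
    def test_two_line_weights_rescale(self):
        grid = default_grid(10.0, 100.0, 0.5)
        vals = np.zeros_like(grid)
        vals[60] = 3.0
        vals[120] = 1.0
        spec = normalize_source(EnergySpectrum(grid, vals))
        # triangle areas keep their 3:1 ratio and sum to one
        total = spec.integrate()
        assert total == pytest.approx(1.0, abs=1e-12)
        assert spec.values[60] / spec.values[120] == pytest.approx(3.0)

    def test_kramers_spectrum_integrates_to_one(self):
        grid = default_grid(10.0, 100.0, 0.1)
        spec = normalize_source(EnergySpectrum(grid, np.clip(100.0 / grid - 1, 0, None)))
        assert spec.integrate() == pytest.approx(1.0, abs=1e-12)

    def test_idempotence_is_exact(self):
        grid = default_grid(10.0, 100.0, 1.0)
        rng = np.random.default_rng(7)
        once = normalize_source(EnergySpectrum(grid, rng.uniform(0.1, 2.0, grid.size)))
        twice = normalize_source(once)
        assert twice is once  # bit-exact: already-normalized spectra pass through

    def test_zero_spectrum_rejected(self):
        with pytest.raises(SpectrumError):
            normalize_source(EnergySpectrum([10.0, 20.0], [0.0, 0.0]))

    def test_shape_unchanged_up_to_scalar(self):
        grid = default_grid(10.0, 100.0, 1.0)
        vals = np.clip(100.0 / grid - 1, 0, None)
        spec = normalize_source(EnergySpectrum(grid, vals))
        ratio = spec.values[vals > 0] / vals[vals > 0]
        assert np.allclose(ratio, ratio[0])


class TestSynthSource:
    def test_continuum_vanishes_at_tube_voltage(self):
        grid = default_grid(10.0, 100.0, 0.1)
        spec = synth_source(100.0, grid)
        assert spec(100.0) == 0.0

    def test_filtration_hardens_the_spectrum(self):
        grid = default_grid(10.0, 100.0, 0.1)
        bare = synth_source(100.0, grid)
        filt = synth_lac(3.0, 0.5, grid)
        hard = synth_source(100.0, grid, filtration=((filt, 0.5),))
        mode_bare = grid[np.argmax(bare.values)]
        mode_hard = grid[np.argmax(hard.values)]
        assert mode_hard > mode_bare

    def test_no_lines_means_single_smooth_hump(self):
        grid = default_grid(10.0, 100.0, 0.1)
        filt = synth_lac(3.0, 0.5, grid)
        spec = synth_source(100.0, grid, filtration=((filt, 0.1),), n_lines=0)
        v = spec.values
        interior_maxima = np.flatnonzero(
            (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
        )
        assert interior_maxima.size <= 1

    def test_empty_grid_rejected(self):
        with pytest.raises(SpectrumError):
            synth_source(100.0, np.array([]))


class TestSynthLac:
    def test_no_jump_is_strictly_decreasing(self):
        grid = default_grid(10.0, 100.0, 0.5)
        spec = synth_lac(1.0, 0.2, grid, kedge_keV=47.0, kedge_jump=1.0)
        assert np.all(np.diff(spec.values) < 0)
        assert spec.edge_energies_keV == ()

    def test_jump_ratio_on_photoelectric_term(self):
        # pre-edge limit comes from one-sided linear extrapolation, whose
        # O(step^2) error is negligible on the default 0.1 keV grid
        grid = default_grid(10.0, 100.0, 0.1)
        spec = synth_lac(1.0, 0.0, grid, kedge_keV=47.0, kedge_jump=5.0)
        assert spec(47.0) / spec(47.0, side="left") == pytest.approx(5.0, rel=1e-3)

    def test_kedge_outside_grid_rejected(self):
        with pytest.raises(SpectrumError):
            synth_lac(1.0, 0.2, default_grid(10, 100, 1.0), kedge_keV=150.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        pe=st.floats(0.0, 10.0),
        compton=st.floats(0.0, 2.0),
        kedge=st.floats(15.0, 95.0),
        jump=st.floats(1.0, 8.0),
    )
    def test_positivity_for_all_valid_parameters(self, pe, compton, kedge, jump):
        if pe == 0.0 and compton == 0.0:
            return
        spec = synth_lac(pe, compton, default_grid(10, 100, 0.5), kedge, jump)
        if pe > 0 or compton > 0:
            assert np.all(spec.values > 0)


class TestMixtureLac:
    def _table(self, scale=1.0):
        grid = default_grid(10.0, 100.0, 1.0)
        return synth_lac(scale * 2.0, scale * 0.2, grid)

    def test_single_component_scales_by_density(self):
        t = self._table()
        mixed = mixture_lac([t], [1.0], 2.5)
        assert np.allclose(mixed.values, 2.5 * t.values)

    def test_fifty_fifty_of_identical_tables_is_identity(self):
        t = self._table()
        mixed = mixture_lac([t, t], [0.5, 0.5], 1.0)
        assert np.allclose(mixed.values, t.values)

    def test_pointwise_weighted_sum(self):
        grid = default_grid(10.0, 100.0, 1.0)
        water = synth_lac(0.032, 0.19, grid)
        heavy = synth_lac(8.0, 0.15, grid, kedge_keV=47.0, kedge_jump=5.5)
        rho, w = 1.2, 0.1
        mixed = mixture_lac([heavy, water], [w, 1 - w], rho)
        for e in (15.0, 33.0, 47.0, 60.0, 99.0):
            expect = rho * (w * heavy(e) + (1 - w) * water(e))
            assert mixed(e) == pytest.approx(expect, rel=1e-12)
        assert 47.0 in mixed.edge_energies_keV

    def test_bad_fractions_rejected(self):
        t = self._table()
        with pytest.raises(SpectrumError):
            mixture_lac([t, t], [0.7, 0.7], 1.0)
        with pytest.raises(SpectrumError):
            mixture_lac([t, t], [-0.2, 1.2], 1.0)

    def test_disjoint_grids_rejected(self):
        a = EnergySpectrum([10.0, 20.0], [1.0, 1.0])
        b = EnergySpectrum([50.0, 60.0], [1.0, 1.0])
        with pytest.raises(SpectrumError):
            mixture_lac([a, b], [0.5, 0.5], 1.0)


class TestSpectrumCsv:
    def test_round_trip_is_bit_identical(self, tmp_path):
        grid = default_grid(10.0, 100.0, 0.09)
        spec = synth_lac(0.7, 0.2, grid, kedge_keV=33.2, kedge_jump=5.5)
        path = tmp_path / "lac.csv"
        write_spectrum_csv(spec, path, metadata={"kind": "lac"})
        back, meta = read_spectrum_csv(path, return_metadata=True)
        assert np.array_equal(back.energies_keV, spec.energies_keV)
        assert np.array_equal(back.values, spec.values)
        assert back.edge_energies_keV == spec.edge_energies_keV
        assert meta["kind"] == "lac"

    def test_small_table_reads(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("energy_keV,value\n10,0.1\n20,0.2\n")
        spec = read_spectrum_csv(path)
        assert spec.energies_keV.size == 2

    def test_out_of_order_rows_error_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("energy_keV,value\n10,0.1\n30,0.2\n20,0.3\n")
        with pytest.raises(SpectrumError, match="line 4"):
            read_spectrum_csv(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("kev,val\n10,0.1\n")
        with pytest.raises(SpectrumError):
            read_spectrum_csv(path)


class TestScannerGeometry:
    def test_nyquist_from_pitch(self):
        assert ScannerGeometry(delta_cm=0.01).nyquist_per_cm == pytest.approx(50.0)

    def test_detector_positions_symmetric_about_axis(self):
        t = ScannerGeometry(n_detectors=8, delta_cm=0.5).detector_positions_cm
        assert np.allclose(t + t[::-1], 0.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ScannerGeometry(delta_cm=-1.0)
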