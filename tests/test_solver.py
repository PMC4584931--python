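import math

import numpy as np
import pytest

from transdentin.analytic import PlaneSourceProblem, series_concentration
from transdentin.solver import (
    HorizonError,
    SourceSpec,
    TubuleGeometry,
    build_grid,
    convergence_study,
    simulate,
    time_to_ratio,
)

PROTEIN_D = 1.36e-10


def frustum_volume(length, d1, d2):
    return math.pi * length / 12.0 * (d1 * d1 + d1 * d2 + d2 * d2)


class TestGeometryAndGrid:
    def test_default_tubule_volume(self):
        geometry = TubuleGeometry()
        expected = frustum_volume(2.5e-3, 1e-6, 3e-6)  # 8.51e3 um^3
        assert geometry.volume == pytest.approx(expected, rel=1e-12)
        assert geometry.volume * 1e18 == pytest.approx(8.508e3, rel=1e-3)

    @pytest.mark.parametrize("n_cells", [10, 137, 500])
    def test_cell_volumes_telescope_to_frustum(self, n_cells):
        geometry = TubuleGeometry()
        grid = build_grid(geometry, n_cells)
        assert grid.volumes.sum() == pytest.approx(geometry.volume, rel=1e-12)

    def test_cylinder_has_equal_face_areas(self):
        geometry = TubuleGeometry(diameter_dej=2e-6, diameter_pulp=2e-6)
        grid = build_grid(geometry, 50)
        assert np.allclose(grid.face_areas, grid.face_areas[0])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            build_grid(TubuleGeometry(), 5)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            TubuleGeometry(length=-1.0)
        with pytest.raises(ValueError):
            TubuleGeometry(diameter_dej=0.0)


class TestSimulate:
    def test_mass_conserved_to_roundoff(self, conical_result):
        assert abs(conical_result.mass_drift) < 1e-10

    def test_concentrations_bounded_by_initial(self, conical_result):
        profile = conical_result.profiles[-1]
        assert np.all(profile.concentrations >= 0.0)
        assert np.all(profile.concentrations <= 0.10 * (1 + 1e-9))

    def test_long_time_limit_reaches_well_mixed_value(self, conical_result):
        geometry = TubuleGeometry()
        source = SourceSpec(initial_concentration=0.10)
        expected = source.total_mass(geometry) / geometry.volume
        profile = conical_result.profiles[-1]  # t* = 3
        assert np.allclose(profile.concentrations, expected, rtol=1e-4)

    def test_linearity_in_initial_concentration(self):
        geometry = TubuleGeometry()
        t_out = [0.1 * geometry.length**2 / PROTEIN_D]
        base = simulate(geometry, SourceSpec(0.05), PROTEIN_D, t_out, n_cells=80)
        scaled = simulate(geometry, SourceSpec(0.15), PROTEIN_D, t_out, n_cells=80)
        np.testing.assert_allclose(
            scaled.profiles[0].concentrations,
            3.0 * base.profiles[0].concentrations,
            rtol=1e-12,
        )

    def test_uniform_cylinder_matches_cosine_series(self):
        """Oracle equivalence: finite volumes vs the plane-source series."""
        geometry = TubuleGeometry(diameter_dej=1e-6, diameter_pulp=1e-6)
        source = SourceSpec(initial_concentration=1.0, source_length_fraction=0.01)
        diffusivity = 4.5e-10
        t_stars = (0.05, 0.15, 0.5, 2.0)
        times = [s * geometry.length**2 / diffusivity for s in t_stars]
        result = simulate(geometry, source, diffusivity, times, n_cells=500)
        problem = PlaneSourceProblem(
            amount_per_area=source.total_mass(geometry) / geometry.area_at(0.0),
            length=geometry.length,
            diffusivity=diffusivity,
        )
        for profile in result.profiles:
            exact = series_concentration(problem, profile.x, profile.time)
            deviation = np.max(np.abs(profile.concentrations - exact))
            assert deviation / problem.final_concentration < 0.01

    def test_pulp_ratio_nondecreasing_and_bounded(self, conical_curve):
        ratio = conical_curve.ratio
        assert np.all(ratio >= 0.0) and np.all(ratio <= 1.0 + 1e-6)
        assert np.all(np.diff(ratio) >= -1e-12)

    def test_slow_protein_observations_logged(self, conical_curve):
        # First molecules arrive by ~2 h, but the plateau takes far longer:
        # qualitative behaviour of the slow (BMP-7-like) reference protein.
        two_hours_t_star = PROTEIN_D * 2 * 3600 / (2.5e-3) ** 2
        ratio_2h = float(np.interp(two_hours_t_star, conical_curve.t_star, conical_curve.ratio))
        assert 0.0 < ratio_2h < 1.0
        ten_hours_t_star = PROTEIN_D * 10 * 3600 / (2.5e-3) ** 2
        ratio_10h = float(np.interp(ten_hours_t_star, conical_curve.t_star, conical_curve.ratio))
        print(f"pulp ratio at 2 h: {ratio_2h:.3f}; at 10 h: {ratio_10h:.5f}")
        assert ratio_10h < 1.0

    def test_invalid_inputs(self):
        geometry = TubuleGeometry()
        with pytest.raises(ValueError):
            simulate(geometry, SourceSpec(0.1), -1e-10, [1.0])
        with pytest.raises(ValueError):
            simulate(geometry, SourceSpec(0.1), 1e-10, [])
        with pytest.raises(ValueError):
            SourceSpec(initial_concentration=0.1, source_length_fraction=1.5)


class TestTimeToRatio:
    def test_exact_sample_returns_its_time(self, conical_curve):
        idx = np.searchsorted(conical_curve.ratio, 0.5)
        target = float(conical_curve.ratio[idx])
        assert time_to_ratio(conical_curve, target) == pytest.approx(
            float(conical_curve.times[idx])
        )

    def test_unreached_ratio_raises_horizon_error(self):
        geometry = TubuleGeometry()
        short = simulate(
            geometry,
            SourceSpec(0.1),
            PROTEIN_D,
            [0.01 * geometry.length**2 / PROTEIN_D],
            n_cells=60,
        )
        with pytest.raises(HorizonError, match="last achieved"):
            time_to_ratio(short.pulp_curve, 0.9)

    def test_faster_diffusion_crosses_sooner(self):
        geometry = TubuleGeometry()
        t_end = 1.0 * geometry.length**2 / PROTEIN_D
        slow = simulate(geometry, SourceSpec(0.1), PROTEIN_D, [t_end], n_cells=80)
        fast = simulate(geometry, SourceSpec(0.1), 2 * PROTEIN_D, [t_end], n_cells=80)
        for target in (0.3, 0.5, 0.8):
            assert time_to_ratio(fast.pulp_curve, target) < time_to_ratio(
                slow.pulp_curve, target
            )

    def test_rejects_out_of_range_targets(self, conical_curve):
        with pytest.raises(ValueError):
            time_to_ratio(conical_curve, 1.5)


class TestConvergence:
    def test_uniform_cylinder_error_decays_at_second_order(self):
        geometry = TubuleGeometry(diameter_dej=1e-6, diameter_pulp=1e-6)
        report = convergence_study(
            geometry,
            SourceSpec(initial_concentration=1.0, source_length_fraction=0.05),
            diffusivity=4.5e-10,
            cell_counts=(50, 100, 200),
            diffusion_number_caps=(100.0, 50.0),
        )
        assert report.monotone
        assert all(a > b for a, b in zip(report.errors[:-1], report.errors[1:]))
        assert 1.7 <= report.observed_order <= 2.3

    def test_recommended_settings_are_ratio_stable(self):
        geometry = TubuleGeometry()
        report = convergence_study(
            geometry,
            SourceSpec(initial_concentration=0.1),
            diffusivity=PROTEIN_D,
            cell_counts=(50, 100, 200),
            diffusion_number_caps=(100.0, 50.0),
        )
        assert report.recommended_n_cells in report.cell_counts
        # halving the time step at the recommended cap barely moves the ratio
        assert abs(report.time_step_ratios[-1] - report.time_step_ratios[0]) < 0.005 * abs(
            report.time_step_ratios[-1]
        )

    def test_requires_three_grid_levels(self):
        with pytest.raises(ValueError):
            convergence_study(
                TubuleGeometry(), SourceSpec(0.1), PROTEIN_D, cell_counts=(50, 100)
            )
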