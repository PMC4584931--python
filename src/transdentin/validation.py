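"""Self-validation suite: oracle equivalence and conservation checks.

Bundled so the command-line ``validate`` subcommand and the test suite run
the identical checks.  Each check returns the measured figure together with
the bound it must satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analytic import PlaneSourceProblem, series_concentration
from .solver import SourceSpec, TubuleGeometry, simulate

__all__ = ["CheckResult", "oracle_equivalence", "mass_conservation", "run_all"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    value: float
    bound: float

    @property
    def passed(self) -> bool:
        return self.value <= self.bound


def oracle_equivalence(
    n_cells: int = 500,
    t_stars=(0.05, 0.15, 0.5, 2.0),
    diffusivity: float = 4.5e-10,
    bound: float = 0.01,
) -> CheckResult:
    """Finite-volume solver vs the plane-source cosine series on a uniform
    cylinder: maximum deviation over all probed (x, t), relative to the
    final concentration M_t.  A thin slug (1% of the length) stands in for
    the plane source."""
    geometry = TubuleGeometry(length=2.5e-3, diameter_dej=1e-6, diameter_pulp=1e-6)
    source = SourceSpec(initial_concentration=1.0, source_length_fraction=0.01)
    times = [s * geometry.length**2 / diffusivity for s in t_stars]
    result = simulate(geometry, source, diffusivity, times, n_cells=n_cells)
    problem = PlaneSourceProblem(
        amount_per_area=source.total_mass(geometry) / geometry.area_at(0.0),
        length=geometry.length,
        diffusivity=diffusivity,
    )
    worst = 0.0
    for profile in result.profiles:
        exact = series_concentration(problem, profile.x, profile.time)
        deviation = np.max(np.abs(profile.concentrations - exact))
        worst = max(worst, float(deviation / problem.final_concentration))
    return CheckResult(name="oracle_equivalence_max_rel_dev", value=worst, bound=bound)


def mass_conservation(
    n_cells: int = 300, t_star_end: float = 2.0, bound: float = 1e-10
) -> CheckResult:
    """Relative drift of the discrete mass over a full conical run."""
    geometry = TubuleGeometry()
    source = SourceSpec(initial_concentration=0.10)
    diffusivity = 1.36e-10
    t_end = t_star_end * geometry.length**2 / diffusivity
    result = simulate(geometry, source, diffusivity, [t_end], n_cells=n_cells)
    return CheckResult(
        name="mass_conservation_rel_drift", value=abs(result.mass_drift), bound=bound
    )


def run_all() -> list:
    return [oracle_equivalence(), mass_conservation()]
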