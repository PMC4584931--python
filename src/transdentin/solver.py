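"""Transient 1-D finite-volume diffusion solver on a conical dentinal tubule.

The tubule is a truncated cone: narrow at the dentin-enamel junction (DEJ,
``x = 0``) and wide at the pulpal end (``x = L``), with the diameter varying
linearly in between.  Transport is pure diffusion of a dissolved agent in the
stagnant dentinal fluid (no outward fluid flow, no wall adsorption, no
reactions), governed by the variable-area diffusion equation

    dC/dt = (1/A(x)) * d/dx ( A(x) * D * dC/dx ),   A(x) = pi d(x)^2 / 4,

with zero-flux boundaries at both ends.  The initial condition is a uniform
slug of concentration C0 occupying the first ``source_length_fraction`` of
the tubule at the DEJ end; the slug is laid down with exact partial-cell
frustum volumes so the initial mass is independent of the grid.

Discretisation: cell-centred finite volumes on a uniform grid with face-area
weighting (conservative by construction; discrete mass is constant to
round-off), Crank-Nicolson time stepping with a short backward-Euler ramp to
damp the sharp initial front, and a geometric time-step ramp capped at a
prescribed diffusion number ``D*dt/dx^2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TubuleGeometry",
    "SourceSpec",
    "Grid",
    "ConcentrationProfile",
    "PulpCurve",
    "SimulationResult",
    "ConvergenceReport",
    "SolverError",
    "HorizonError",
    "build_grid",
    "simulate",
    "time_to_ratio",
    "convergence_study",
]

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Numerical instability detected during time stepping."""


class HorizonError(RuntimeError):
    """A requested pulp-curve ratio was not reached within the simulated horizon."""


@dataclass(frozen=True)
class TubuleGeometry:
    """Conical tubule geometry (SI units).

    Defaults are the canonical dentinal tubule: 2.5 mm long, 1 um diameter at
    the DEJ and 3 um at the pulpal end.
    """

    length: float = 2.5e-3
    diameter_dej: float = 1.0e-6
    diameter_pulp: float = 3.0e-6

    def __post_init__(self) -> None:
        for name in ("length", "diameter_dej", "diameter_pulp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def diameter_at(self, x):
        """Local diameter, linear between the two ends."""
        return self.diameter_dej + (self.diameter_pulp - self.diameter_dej) * (
            np.asarray(x) / self.length
        )

    def area_at(self, x):
        return math.pi / 4.0 * self.diameter_at(x) ** 2

    def segment_volume(self, x0, x1):
        """Exact frustum volume of the segment [x0, x1]."""
        d0 = self.diameter_at(x0)
        d1 = self.diameter_at(x1)
        return math.pi * (np.asarray(x1) - np.asarray(x0)) / 12.0 * (
            d0 * d0 + d0 * d1 + d1 * d1
        )

    @property
    def volume(self) -> float:
        """Total tubule volume (pi L / 12)(d1^2 + d1 d2 + d2^2)."""
        return float(self.segment_volume(0.0, self.length))


@dataclass(frozen=True)
class SourceSpec:
    """Initial agent slug at the DEJ end.

    ``initial_concentration`` is in mg/mL; ``source_length_fraction`` is the
    fraction of the tubule length the slug occupies (default 5%).
    """

    initial_concentration: float
    source_length_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.initial_concentration <= 0:
            raise ValueError("initial_concentration must be positive")
        if not 0 < self.source_length_fraction <= 1:
            raise ValueError("source_length_fraction must be in (0, 1]")

    def source_volume(self, geometry: TubuleGeometry) -> float:
        """Slug volume V0 (m^3)."""
        return float(
            geometry.segment_volume(0.0, self.source_length_fraction * geometry.length)
        )

    def total_mass(self, geometry: TubuleGeometry) -> float:
        return self.initial_concentration * self.source_volume(geometry)


@dataclass(frozen=True)
class Grid:
    centers: np.ndarray
    faces: np.ndarray
    face_areas: np.ndarray
    volumes: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.centers.size

    @property
    def dx(self) -> float:
        return float(self.faces[1] - self.faces[0])


@dataclass(frozen=True)
class ConcentrationProfile:
    """Spatial concentration field at one output time."""

    x: np.ndarray  # cell centres, m
    volumes: np.ndarray  # cell volumes, m^3
    concentrations: np.ndarray  # mg/mL
    time: float  # s

    @property
    def mass(self) -> float:
        return float(np.dot(self.concentrations, self.volumes))


@dataclass(frozen=True)
class PulpCurve:
    """Concentration at the pulpal end versus time.

    ``final_value`` is the well-mixed limit C_t = total mass / V_t (not the
    last sample); ``ratio`` is the breakthrough curve C(L, t)/C_t and
    ``t_star`` the matching dimensionless time D*t/L^2.
    """

    times: np.ndarray  # s
    concentrations: np.ndarray  # mg/mL
    final_value: float  # C_t, mg/mL
    t_star: np.ndarray
    diffusivity: float
    length: float

    @property
    def ratio(self) -> np.ndarray:
        return self.concentrations / self.final_value


@dataclass(frozen=True)
class SimulationResult:
    profiles: list
    pulp_curve: PulpCurve
    mass_drift: float
    grid: Grid
    config: dict = field(default_factory=dict)


def build_grid(geometry: TubuleGeometry, n_cells: int) -> Grid:
    """Uniform cell-centred grid with exact frustum cell volumes.

    Cell volumes telescope to the exact total frustum volume for any cell
    count.
    """
    if n_cells < 10:
        raise ValueError(f"n_cells must be at least 10, got {n_cells}")
    faces = np.linspace(0.0, geometry.length, n_cells + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    return Grid(
        centers=centers,
        faces=faces,
        face_areas=geometry.area_at(faces),
        volumes=geometry.segment_volume(faces[:-1], faces[1:]),
    )


def _initial_field(geometry: TubuleGeometry, source: SourceSpec, grid: Grid) -> np.ndarray:
    """Volume-exact projection of the slug onto the grid (partial cells get the
    slug's share of their frustum volume, so initial mass is grid-independent)."""
    s = source.source_length_fraction * geometry.length
    lo = np.minimum(grid.faces[:-1], s)
    hi = np.minimum(grid.faces[1:], s)
    overlap = np.where(hi > lo, geometry.segment_volume(lo, hi), 0.0)
    return source.initial_concentration * overlap / grid.volumes


def _diffusion_operator(grid: Grid, diffusivity: float) -> sp.csc_matrix:
    """Conservative FV operator: dC/dt = M C, zero flux at both ends."""
    conduct = diffusivity * grid.face_areas[1:-1] / grid.dx  # interior faces
    n = grid.n_cells
    main = np.zeros(n)
    main[:-1] -= conduct / grid.volumes[:-1]
    main[1:] -= conduct / grid.volumes[1:]
    lower = conduct / grid.volumes[1:]
    upper = conduct / grid.volumes[:-1]
    return sp.diags([lower, main, upper], [-1, 0, 1], format="csc")


def _time_grid(t_end: float, dt_max: float, output_times, ramp_factor=1.05):
    """Geometric ramp from dt_max/200 up to dt_max, landing exactly on every
    requested output time."""
    outputs = sorted(set(float(t) for t in output_times))
    times = [0.0]
    dt = dt_max / 200.0
    while times[-1] < t_end:
        nxt = min(times[-1] + dt, t_end)
        for t_out in outputs:
            if times[-1] < t_out <= nxt:
                nxt = t_out
                break
        times.append(nxt)
        dt = min(dt * ramp_factor, dt_max)
    return np.asarray(times)


def simulate(
    geometry: TubuleGeometry,
    source: SourceSpec,
    diffusivity: float,
    output_times,
    n_cells: int = 500,
    scheme: str = "crank-nicolson",
    diffusion_number_cap: float = 50.0,
    be_ramp_steps: int = 50,
) -> SimulationResult:
    """Integrate the variable-area diffusion equation.

    Parameters
    ----------
    output_times:
        Strictly increasing positive times (s) at which full profiles are
        returned.  The pulp-end curve is recorded at every internal step.
    scheme:
        ``"crank-nicolson"`` (default, second order) or ``"backward-euler"``.
        Crank-Nicolson always starts with ``be_ramp_steps`` backward-Euler
        steps to damp oscillations from the sharp initial front.
    diffusion_number_cap:
        Upper bound on D*dt/dx^2; accuracy, not stability, binds for the
        implicit schemes.

    Returns a :class:`SimulationResult` with the requested profiles, the
    pulp-end :class:`PulpCurve` and the relative mass drift over the run.
    """
    output_times = np.asarray(sorted(float(t) for t in output_times), dtype=float)
    if output_times.size == 0 or output_times[0] <= 0:
        raise ValueError("output_times must be positive")
    if diffusivity <= 0:
        raise ValueError("diffusivity must be positive")
    if scheme not in ("crank-nicolson", "backward-euler"):
        raise ValueError(f"unknown scheme {scheme!r}")

    grid = build_grid(geometry, n_cells)
    operator = _diffusion_operator(grid, diffusivity)
    identity = sp.identity(grid.n_cells, format="csc")
    concentrations = _initial_field(geometry, source, grid)
    mass0 = float(np.dot(concentrations, grid.volumes))

    dt_max = diffusion_number_cap * grid.dx**2 / diffusivity
    times = _time_grid(float(output_times[-1]), dt_max, output_times)

    clip_floor = -1e-12 * source.initial_concentration
    wanted = set(output_times.tolist())
    profiles = []
    pulp = [concentrations[-1]]
    solver_cache: tuple | None = None
    lu = None
    for step in range(1, times.size):
        dt = times[step] - times[step - 1]
        theta = 1.0 if (scheme == "backward-euler" or step <= be_ramp_steps) else 0.5
        if solver_cache != (dt, theta):
            lu = spla.splu((identity - dt * theta * operator).tocsc())
            solver_cache = (dt, theta)
        rhs = concentrations + dt * (1.0 - theta) * (operator @ concentrations)
        concentrations = lu.solve(rhs)
        if not np.all(np.isfinite(concentrations)):
            raise SolverError(f"non-finite concentration at step {step}, t={times[step]:.4g} s")
        worst = float(concentrations.min())
        if worst < clip_floor:
            raise SolverError(
                f"negative concentration {worst:.3e} beyond round-off tolerance "
                f"at step {step}, t={times[step]:.4g} s"
            )
        if worst < 0.0:
            concentrations = np.where(concentrations < 0.0, 0.0, concentrations)
        pulp.append(concentrations[-1])
        if times[step] in wanted:
            profiles.append(
                ConcentrationProfile(
                    x=grid.centers,
                    volumes=grid.volumes,
                    concentrations=concentrations.copy(),
                    time=float(times[step]),
                )
            )

    mass_drift = float(np.dot(concentrations, grid.volumes)) / mass0 - 1.0
    final_value = mass0 / geometry.volume
    curve = PulpCurve(
        times=times,
        concentrations=np.asarray(pulp),
        final_value=final_value,
        t_star=diffusivity * times / geometry.length**2,
        diffusivity=diffusivity,
        length=geometry.length,
    )
    logger.info(
        "simulate: n_cells=%d steps=%d scheme=%s mass_drift=%.3e",
        n_cells,
        times.size - 1,
        scheme,
        mass_drift,
    )
    config = {
        "geometry": {
            "length_m": geometry.length,
            "diameter_dej_m": geometry.diameter_dej,
            "diameter_pulp_m": geometry.diameter_pulp,
        },
        "source": {
            "initial_concentration_mg_per_ml": source.initial_concentration,
            "source_length_fraction": source.source_length_fraction,
        },
        "diffusivity_m2_s": diffusivity,
        "n_cells": n_cells,
        "scheme": scheme,
        "diffusion_number_cap": diffusion_number_cap,
        "be_ramp_steps": be_ramp_steps,
        "n_steps": int(times.size - 1),
        "mass_drift": mass_drift,
    }
    return SimulationResult(
        profiles=profiles, pulp_curve=curve, mass_drift=mass_drift, grid=grid, config=config
    )


def time_to_ratio(curve: PulpCurve, target_ratio: float) -> float:
    """First time (s) the pulp ratio crosses ``target_ratio``, by linear
    interpolation between samples."""
    if not 0 < target_ratio < 1:
        raise ValueError("target_ratio must be in (0, 1)")
    ratio = curve.ratio
    above = np.nonzero(ratio >= target_ratio)[0]
    if above.size == 0:
        raise HorizonError(
            f"ratio {target_ratio} not reached within simulated horizon; "
            f"last achieved ratio {float(ratio[-1]):.4f}"
        )
    idx = int(above[0])
    if idx == 0 or ratio[idx] == target_ratio:
        return float(curve.times[idx])
    t0, t1 = curve.times[idx - 1], curve.times[idx]
    r0, r1 = ratio[idx - 1], ratio[idx]
    return float(t0 + (target_ratio - r0) * (t1 - t0) / (r1 - r0))


@dataclass(frozen=True)
class ConvergenceReport:
    cell_counts: list
    errors: list  # per level, vs oracle (uniform) or vs next-finer grid
    observed_order: float
    pulp_ratios: list  # pulp ratio at the probe t* per level
    time_step_caps: list
    time_step_ratios: list  # pulp ratio at the probe t* per dt cap (finest grid)
    recommended_n_cells: int
    recommended_diffusion_number: float
    monotone: bool


def convergence_study(
    geometry: TubuleGeometry,
    source: SourceSpec,
    diffusivity: float,
    cell_counts=(50, 100, 200, 400),
    diffusion_number_caps=(100.0, 50.0, 25.0),
    probe_t_star: float = 0.15,
    ratio_tolerance: float = 0.005,
) -> ConvergenceReport:
    """Grid- and time-step-dependence study at the probe dimensionless time.

    On a uniform cylinder the spatial error is measured against the exact
    finite-slug cosine series; on conical geometry, against the next-finer
    grid (consecutive differences).  The observed order is the least-squares
    slope of log error vs log cell count (second order expected).  The
    recommended settings are the coarsest whose refinement moves the pulp
    ratio at the probe time by less than ``ratio_tolerance`` (relative).
    """
    cell_counts = sorted(int(n) for n in cell_counts)
    if len(cell_counts) < 3:
        raise ValueError("need at least 3 grid levels")
    t_probe = probe_t_star * geometry.length**2 / diffusivity
    uniform = math.isclose(geometry.diameter_dej, geometry.diameter_pulp)

    fields = {}
    pulp_ratios = []
    for n in cell_counts:
        res = simulate(geometry, source, diffusivity, [t_probe], n_cells=n)
        fields[n] = res.profiles[0]
        pulp_ratios.append(float(res.pulp_curve.ratio[-1]))

    scale = source.total_mass(geometry) / geometry.volume  # C_t
    errors = []
    if uniform:
        from .analytic import PlaneSourceProblem, slug_series_concentration

        problem = PlaneSourceProblem(
            amount_per_area=source.total_mass(geometry) / geometry.area_at(0.0),
            length=geometry.length,
            diffusivity=diffusivity,
        )
        for n in cell_counts:
            prof = fields[n]
            exact = slug_series_concentration(
                problem, source.source_length_fraction, prof.x, t_probe
            )
            errors.append(
                float(np.sqrt(np.mean((prof.concentrations - exact) ** 2)) / scale)
            )
        order_counts, order_errors = cell_counts, errors
    else:
        for coarse, fine in zip(cell_counts[:-1], cell_counts[1:]):
            pc, pf = fields[coarse], fields[fine]
            interp = np.interp(pc.x, pf.x, pf.concentrations)
            errors.append(
                float(np.sqrt(np.mean((pc.concentrations - interp) ** 2)) / scale)
            )
        order_counts, order_errors = cell_counts[:-1], errors

    slope = np.polyfit(np.log(order_counts), np.log(order_errors), 1)[0]
    observed_order = float(-slope)
    monotone = all(a > b for a, b in zip(order_errors[:-1], order_errors[1:]))
    if not monotone:
        logger.warning("convergence_study: non-monotone error decay %s", order_errors)

    # time-step dependence on the finest grid
    caps = list(diffusion_number_caps)
    dt_ratios = []
    for cap in caps:
        res = simulate(
            geometry,
            source,
            diffusivity,
            [t_probe],
            n_cells=cell_counts[-1],
            diffusion_number_cap=cap,
        )
        dt_ratios.append(float(res.pulp_curve.ratio[-1]))

    recommended_n = cell_counts[-1]
    for i in range(len(cell_counts) - 1):
        if abs(pulp_ratios[i + 1] - pulp_ratios[i]) < ratio_tolerance * abs(
            pulp_ratios[i + 1]
        ):
            recommended_n = cell_counts[i]
            break
    recommended_cap = caps[0]
    for i in range(len(caps) - 1):
        if abs(dt_ratios[i + 1] - dt_ratios[i]) > ratio_tolerance * abs(dt_ratios[i + 1]):
            recommended_cap = caps[i + 1]
    return ConvergenceReport(
        cell_counts=cell_counts,
        errors=errors,
        observed_order=observed_order,
        pulp_ratios=pulp_ratios,
        time_step_caps=caps,
        time_step_ratios=dt_ratios,
        recommended_n_cells=recommended_n,
        recommended_diffusion_number=recommended_cap,
        monotone=monotone,
    )
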