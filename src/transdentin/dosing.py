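"""Dose planning: from a required pulpal concentration to the applied dose.

The stepwise procedure:

1. resolve the agent's diffusion coefficient D (registry value, Stokes
   radius, or molecular weight);
2. accept the required pulpal concentration C_r and the acceptable time t;
3. form the dimensionless time t* = D*t/L^2;
4. evaluate the breakthrough correlation ratio = C/C_t at t*;
5. the final (well-mixed) concentration must then be C_t = C_r / ratio;
6. mass balance C0*V0 = C_t*V_t gives the initial concentration C0 to apply
   in the source volume V0 at the dentin-enamel junction.

The *critical time* of an agent is the inverse question: how long until the
pulpal concentration reaches a stated fraction (0.25 by convention) of its
final value; t_r = invert(ratio) * L^2 / D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import correlation
from .correlation import CorrelationParams, DEFAULT_PARAMS
from .molecules import (
    DEFAULT_SOLVENT,
    Molecule,
    Solvent,
    get_agent,
    load_agent_registry,
    resolve_diffusion_coefficient,
)
from .solver import SourceSpec, TubuleGeometry

__all__ = [
    "DosePlan",
    "plan_dose",
    "critical_time",
    "critical_time_report",
    "tubule_volume",
]


def tubule_volume(geometry: TubuleGeometry) -> float:
    """Frustum volume (pi L / 12)(d1^2 + d1 d2 + d2^2) in m^3."""
    return geometry.volume


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _as_molecule(agent, solvent: Solvent) -> Molecule:
    if isinstance(agent, str):
        agent = get_agent(agent)
    return resolve_diffusion_coefficient(agent, solvent)


@dataclass(frozen=True)
class DosePlan:
    """Audit record of one pass through the stepwise procedure (SI + mg/mL)."""

    agent: Molecule
    required_pulpal_concentration: float  # C_r, mg/mL
    acceptable_time: float  # s
    geometry: TubuleGeometry
    t_star: float
    ratio: float  # C/C_t at t_star
    final_concentration: float  # C_t, mg/mL
    source_volume: float  # V0, m^3
    tubule_volume: float  # V_t, m^3
    initial_concentration: float  # C0, mg/mL
    params: CorrelationParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        # audit identity C0*V0 = C_t*V_t, and the ordering it implies
        lhs = self.initial_concentration * self.source_volume
        rhs = self.final_concentration * self.tubule_volume
        if not math.isclose(lhs, rhs, rel_tol=1e-12):
            raise ValueError("mass balance C0*V0 = C_t*V_t violated")
        if not (
            self.initial_concentration
            >= self.final_concentration
            >= self.required_pulpal_concentration
            > 0
        ):
            raise ValueError("expected C0 >= C_t >= C_r > 0")

    def as_dict(self) -> dict:
        return {
            "agent": self.agent.name,
            "diffusion_coefficient_m2_s": self.agent.diffusion_coefficient,
            "required_pulpal_concentration_mg_per_ml": self.required_pulpal_concentration,
            "acceptable_time_s": self.acceptable_time,
            "tubule_length_m": self.geometry.length,
            "t_star": self.t_star,
            "ratio_c_over_ct": self.ratio,
            "final_concentration_mg_per_ml": self.final_concentration,
            "source_volume_m3": self.source_volume,
            "tubule_volume_m3": self.tubule_volume,
            "initial_concentration_mg_per_ml": self.initial_concentration,
            "correlation_provenance": self.params.provenance,
        }


def _feasible_time_window(diffusivity: float, length: float, params: CorrelationParams):
    lo = params.validity[0] * length**2 / diffusivity
    hi = correlation.saturation_t_star(params) * length**2 / diffusivity
    return lo, hi


def plan_dose(
    agent,
    required_concentration: float,
    acceptable_time: float,
    geometry: TubuleGeometry = TubuleGeometry(),
    source_length_fraction: float = 0.05,
    params: CorrelationParams = DEFAULT_PARAMS,
    solvent: Solvent = DEFAULT_SOLVENT,
) -> DosePlan:
    """Run the stepwise procedure for one agent.

    *agent* may be a registry name or a :class:`Molecule` (resolved here if
    needed).  ``required_concentration`` (C_r) is in mg/mL and
    ``acceptable_time`` in seconds.  Raises
    :class:`~transdentin.correlation.ValidityRangeError` with the feasible
    time window if the requested time falls outside the correlation's range.
    """
    if required_concentration <= 0:
        raise ValueError("required_concentration must be positive")
    if acceptable_time <= 0:
        raise ValueError("acceptable_time must be positive")
    molecule = _as_molecule(agent, solvent)
    diffusivity = molecule.diffusion_coefficient
    t_star = correlation.dimensionless_time(diffusivity, acceptable_time, geometry.length)
    try:
        ratio = float(correlation.ratio_at(t_star, params))
    except correlation.ValidityRangeError as err:
        lo, hi = _feasible_time_window(diffusivity, geometry.length, params)
        raise correlation.ValidityRangeError(
            f"{err}; feasible acceptable_time for {molecule.name!r} is "
            f"[{lo:.0f}, {hi:.0f}] s"
        ) from err
    final_concentration = required_concentration / ratio
    v_t = geometry.volume
    v_0 = SourceSpec(
        initial_concentration=1.0, source_length_fraction=source_length_fraction
    ).source_volume(geometry)
    initial_concentration = final_concentration * v_t / v_0
    return DosePlan(
        agent=molecule,
        required_pulpal_concentration=required_concentration,
        acceptable_time=acceptable_time,
        geometry=geometry,
        t_star=t_star,
        ratio=ratio,
        final_concentration=final_concentration,
        source_volume=v_0,
        tubule_volume=v_t,
        initial_concentration=initial_concentration,
        params=params,
    )


def critical_time(
    agent,
    geometry: TubuleGeometry = TubuleGeometry(),
    ratio: float = 0.25,
    params: CorrelationParams = DEFAULT_PARAMS,
    solvent: Solvent = DEFAULT_SOLVENT,
    rounded: bool = True,
):
    """Time for the pulpal concentration to reach ``ratio`` of its final value.

    ``t_r = invert(ratio) * L^2 / D``, reported in minutes (half-up rounded
    by default, matching how critical times are tabulated).
    """
    molecule = _as_molecule(agent, solvent)
    t_star = correlation.invert(ratio, params)
    minutes = t_star * geometry.length**2 / molecule.diffusion_coefficient / 60.0
    return _round_half_up(minutes) if rounded else minutes


def critical_time_report(
    registry=None,
    geometry: TubuleGeometry = TubuleGeometry(),
    ratio: float = 0.25,
    params: CorrelationParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Critical-time table for every registry agent, one row each.

    Rows are in registry order; since t_r is proportional to 1/D, ascending
    diffusion coefficient means descending critical time.
    """
    agents = registry if registry is not None else load_agent_registry()
    t_star = correlation.invert(ratio, params)
    rows = []
    for agent in agents:
        molecule = _as_molecule(agent, DEFAULT_SOLVENT)
        minutes = t_star * geometry.length**2 / molecule.diffusion_coefficient / 60.0
        rows.append(
            {
                "name": molecule.name,
                "molecular_weight_da": molecule.molecular_weight,
                "diffusion_coefficient_m2_s": molecule.diffusion_coefficient,
                "critical_time_min": _round_half_up(minutes),
                "critical_time_min_exact": minutes,
            }
        )
    return pd.DataFrame(rows)
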