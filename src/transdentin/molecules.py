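"""Molecular transport properties of therapeutic agents.

A therapeutic agent is characterised by at most three numbers: its molecular
weight ``M_w`` (Da), its Stokes radius ``R_s`` (nm) and its diffusion
coefficient ``D`` (m^2/s) in the dentinal fluid (taken as water at body
temperature).  Any one of them is enough:

* the minimal hydrodynamic radius of a globular molecule follows from its
  weight, ``R_min = 0.066 * M_w**(1/3)`` nm, assuming the density of a
  smooth protein sphere;
* the diffusion coefficient follows from the radius through the
  Stokes-Einstein relation ``D = k_B*T / (6*pi*mu*R_s)``.

A packaged registry ships the eight reference agents (restorative-material
monomers, ions released by liners and bases, and the growth factors TGF-beta
and BMP-7) with their literature diffusion coefficients; registry values are
authoritative and are never overwritten by recomputation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from functools import lru_cache

from scipy.constants import k as BOLTZMANN_J_PER_K

__all__ = [
    "Molecule",
    "Solvent",
    "WATER_37C_CALIBRATED",
    "WATER_37C_HANDBOOK",
    "DEFAULT_SOLVENT",
    "UnknownAgentError",
    "estimate_min_radius",
    "stokes_einstein",
    "load_agent_registry",
    "get_agent",
    "resolve_diffusion_coefficient",
]

#: Coefficient of the minimal-radius relation, nm per Da^(1/3).
MIN_RADIUS_COEFF_NM = 0.066


class UnknownAgentError(KeyError):
    """Raised when a registry lookup does not match any packaged agent."""


@dataclass(frozen=True)
class Solvent:
    """Solvent state entering the Stokes-Einstein relation.

    Parameters
    ----------
    temperature:
        Absolute temperature in kelvin.
    viscosity:
        Dynamic viscosity in Pa*s.
    """

    temperature: float
    viscosity: float
    boltzmann_constant: float = BOLTZMANN_J_PER_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")


#: Water at 37 C with the viscosity calibrated so that R_s = 2.2 nm maps to
#: D = 1.36e-10 m^2/s, the value used throughout the dosing worked example.
WATER_37C_CALIBRATED = Solvent(temperature=310.15, viscosity=7.59e-4)

#: Water at 37 C with the handbook viscosity (gives 1.49e-10 m^2/s for 2.2 nm).
WATER_37C_HANDBOOK = Solvent(temperature=310.15, viscosity=6.91e-4)

DEFAULT_SOLVENT = WATER_37C_CALIBRATED


@dataclass(frozen=True)
class Molecule:
    """An agent's identity and transport properties.

    All numeric fields are optional at construction; a molecule is *resolved*
    once its ``diffusion_coefficient`` is set (see
    :func:`resolve_diffusion_coefficient`).
    """

    name: str
    group: str = ""
    molecular_weight: float | None = None  # Da
    stokes_radius: float | None = None  # nm
    diffusion_coefficient: float | None = None  # m^2/s
    notes: str = ""

    def __post_init__(self) -> None:
        for field in ("molecular_weight", "stokes_radius", "diffusion_coefficient"):
            value = getattr(self, field)
            if value is not None and value <= 0:
                raise ValueError(f"{field} must be positive, got {value}")

    @property
    def is_resolved(self) -> bool:
        return self.diffusion_coefficient is not None


def estimate_min_radius(molecular_weight: float) -> float:
    """Minimal radius R_min (nm) of a smooth sphere of the given mass (Da).

    R_min is the radius a globular molecule would have if it were a smooth
    sphere of typical protein density; it is a lower bound on the Stokes
    radius and may substitute for it when R_s is unknown.
    """
    if molecular_weight <= 0:
        raise ValueError(f"molecular_weight must be positive, got {molecular_weight}")
    return MIN_RADIUS_COEFF_NM * molecular_weight ** (1.0 / 3.0)


def stokes_einstein(stokes_radius: float, solvent: Solvent = DEFAULT_SOLVENT) -> float:
    """Diffusion coefficient (m^2/s) from the Stokes-Einstein relation.

    ``D = k_B*T / (6*pi*mu*R_s)`` with the radius given in nanometres and the
    result returned in SI units.
    """
    if stokes_radius <= 0:
        raise ValueError(f"stokes_radius must be positive, got {stokes_radius}")
    import math

    radius_m = stokes_radius * 1e-9
    return (
        solvent.boltzmann_constant
        * solvent.temperature
        / (6.0 * math.pi * solvent.viscosity * radius_m)
    )


@lru_cache(maxsize=1)
def _registry_rows() -> tuple[Molecule, ...]:
    text = resources.files("transdentin.data").joinpath("agents.csv").read_text()
    reader = csv.DictReader(text.splitlines())
    agents = []
    for row in reader:
        agents.append(
            Molecule(
                name=row["name"],
                group=row["group"],
                molecular_weight=float(row["molecular_weight_da"]),
                diffusion_coefficient=float(row["diffusion_coefficient_m2_s"]),
                notes=row["formula"],
            )
        )
    return tuple(agents)


def load_agent_registry() -> list[Molecule]:
    """The eight packaged reference agents with literature D values."""
    return list(_registry_rows())


_ALIASES = {
    "tegdma": "tegdma",
    "triethylene glycol dimethacrylate": "tegdma",
    "hema": "hema",
    "2-hydroxyethyl methacrylate": "hema",
    "fluoride": "fluoride ions",
    "f-": "fluoride ions",
    "eugenol": "eugenol",
    "4-allyl-2-methoxyphenol": "eugenol",
    "calcium": "calcium ions",
    "ca++": "calcium ions",
    "si": "silicon",
    "tgf-beta": "transforming growth factor-beta",
    "tgf-b": "transforming growth factor-beta",
    "transforming growth factor beta": "transforming growth factor-beta",
    "bmp-7": "bone morphogenetic protein 7",
    "bmp7": "bone morphogenetic protein 7",
}


def get_agent(name: str) -> Molecule:
    """Case-insensitive registry lookup; raises :class:`UnknownAgentError`."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    for agent in _registry_rows():
        if agent.name.lower() == key:
            return agent
    valid = ", ".join(agent.name for agent in _registry_rows())
    raise UnknownAgentError(f"unknown agent {name!r}; valid names: {valid}")


def resolve_diffusion_coefficient(
    molecule: Molecule, solvent: Solvent = DEFAULT_SOLVENT
) -> Molecule:
    """Return a copy of *molecule* with its diffusion coefficient set.

    Resolution priority is D > R_s > M_w: an explicit diffusion coefficient is
    kept untouched; otherwise a missing Stokes radius is estimated by the
    minimal-radius relation (R_min substituting for R_s) and D follows from
    Stokes-Einstein.  Resolving twice is idempotent.
    """
    if molecule.diffusion_coefficient is not None:
        return molecule
    radius = molecule.stokes_radius
    mol = molecule
    if radius is None:
        if molecule.molecular_weight is None:
            raise ValueError(
                f"molecule {molecule.name!r} has none of D, stokes_radius, "
                "molecular_weight set"
            )
        radius = estimate_min_radius(molecule.molecular_weight)
        mol = replace(mol, stokes_radius=radius)
    return replace(mol, diffusion_coefficient=stokes_einstein(radius, solvent))
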