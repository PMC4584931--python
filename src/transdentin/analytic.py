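"""Closed-form diffusion solutions used as the oracle for the numerical solver.

The reference problem is a plane source of strength ``M`` (mass per unit
cross-section area) released at the sealed end ``x = 0`` of a closed tube of
length ``L`` (zero-flux boundaries at both ends, matching the assumption of
no dentinal fluid outflow).  The transient field is the cosine eigenfunction
series

    C(x, t) = (2M/L) * sum_{n>=1} exp(-(n*pi/L)^2 * D * t) * cos(n*pi*x/L) + M_t

with the well-mixed limit ``M_t = M/L``.  A finite-width variant (uniform
slug occupying the first fraction ``f`` of the tube) replaces the mode
amplitudes ``2M/L`` by ``2*C0*sin(n*pi*f)/(n*pi)`` and is the exact solution
matched by the finite-volume solver's initial condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlaneSourceProblem",
    "fick_flux",
    "series_concentration",
    "slug_series_concentration",
    "pulp_ratio_uniform",
    "profile_table",
]

logger = logging.getLogger(__name__)

_MAX_TERMS = 100_000


@dataclass(frozen=True)
class PlaneSourceProblem:
    """Plane source diffusing in a closed uniform tube.

    Parameters
    ----------
    amount_per_area:
        Total released amount M per unit cross-section area (e.g. mg/m^2).
    length:
        Tube length L in metres.
    diffusivity:
        Diffusion coefficient D in m^2/s.
    """

    amount_per_area: float
    length: float
    diffusivity: float

    def __post_init__(self) -> None:
        for field in ("amount_per_area", "length", "diffusivity"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")

    @property
    def final_concentration(self) -> float:
        """Well-mixed limit M_t = M / L."""
        return self.amount_per_area / self.length


def fick_flux(diffusivity: float, concentration_gradient) -> float:
    """Steady diffusive flux ``j = -D * dC/dx`` (positive down-gradient)."""
    if diffusivity <= 0:
        raise ValueError(f"diffusivity must be positive, got {diffusivity}")
    return -diffusivity * np.asarray(concentration_gradient)


def _series_sum(x, t, length, diffusivity, amplitudes, tolerance, scale):
    """Sum cos-series with term-n amplitude amplitudes(n), truncated when the
    remaining-term bound falls below tolerance*scale."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for n in range(1, _MAX_TERMS + 1):
        damping = math.exp(-((n * math.pi / length) ** 2) * t * diffusivity)
        amp = amplitudes(n)
        if abs(amp) * damping < tolerance * scale:
            break
        total += amp * damping * np.cos(n * math.pi * x / length)
    else:
        raise ValueError(
            "series did not converge within the term cap; "
            f"t*D/L^2 = {t * diffusivity / length**2:.2e} is too small"
        )
    return total


def series_concentration(
    problem: PlaneSourceProblem, x, t: float, tolerance: float = 1e-10
):
    """Evaluate the plane-source cosine series C(x, t).

    ``x`` may be a scalar or array of positions in [0, L]; ``t`` must be
    strictly positive (the series does not converge pointwise at the initial
    instant).  Small negative ringing within ``tolerance`` of zero is clipped
    to zero and logged.
    """
    x = np.asarray(x, dtype=float)
    if t <= 0:
        raise ValueError("t must be strictly positive for the series solution")
    if np.any(x < 0) or np.any(x > problem.length):
        raise ValueError("x must lie in [0, L]")
    m_t = problem.final_concentration
    amp = 2.0 * problem.amount_per_area / problem.length
    values = _series_sum(
        x, t, problem.length, problem.diffusivity, lambda n: amp, tolerance, m_t
    ) + m_t
    negative = values < 0
    if np.any(negative):
        worst = float(values.min())
        if worst < -tolerance * m_t:
            raise ValueError(f"series produced a non-small negative value {worst}")
        logger.debug("clipping series ringing (min %.3e) to zero", worst)
        values = np.where(negative, 0.0, values)
    return values if values.ndim else float(values)


def slug_series_concentration(
    problem: PlaneSourceProblem,
    source_fraction: float,
    x,
    t: float,
    tolerance: float = 1e-10,
):
    """Exact series for a finite slug filling the first ``source_fraction`` of
    the tube at concentration ``C0 = M / (f*L)``; tends to the plane-source
    series as the fraction goes to zero.  Used as the solver's convergence
    oracle on uniform geometry.
    """
    if not 0 < source_fraction <= 1:
        raise ValueError("source_fraction must be in (0, 1]")
    if t <= 0:
        raise ValueError("t must be strictly positive for the series solution")
    m_t = problem.final_concentration
    c0 = problem.amount_per_area / (source_fraction * problem.length)

    def amplitude(n: int) -> float:
        return 2.0 * c0 * math.sin(n * math.pi * source_fraction) / (n * math.pi)

    values = _series_sum(
        x, t, problem.length, problem.diffusivity, amplitude, tolerance, m_t
    ) + m_t
    values = np.where(values < 0, 0.0, values)
    return values if values.ndim else float(values)


def pulp_ratio_uniform(t_star: float, tolerance: float = 1e-10) -> float:
    """Normalized pulpal-end concentration C(L, t*)/M_t of the uniform tube.

    Equals ``1 + 2*sum_n (-1)^n exp(-n^2 pi^2 t*)``; strictly increasing in
    the dimensionless time ``t* = D*t/L^2`` and approaching 1 from below.
    """
    if t_star <= 0:
        raise ValueError("t_star must be strictly positive")
    total = 1.0
    for n in range(1, _MAX_TERMS + 1):
        term = 2.0 * math.exp(-(n * math.pi) ** 2 * t_star)
        if term < tolerance:
            break
        total += term if n % 2 == 0 else -term
    else:
        raise ValueError(f"series did not converge within the term cap at t*={t_star}")
    return max(total, 0.0)


def profile_table(problem: PlaneSourceProblem, t: float, n_points: int = 101):
    """Two-column (x/L, C) table of the series profile for export/plotting."""
    import pandas as pd

    xs = np.linspace(0.0, problem.length, n_points)
    return pd.DataFrame(
        {
            "x_over_L": xs / problem.length,
            "concentration": series_concentration(problem, xs, t),
        }
    )
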