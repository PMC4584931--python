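import pytest
from hypothesis import HealthCheck, settings

from transdentin.correlation import fit_params
from transdentin.solver import SourceSpec, TubuleGeometry, simulate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Diffusivity of the slow reference protein (BMP-7-like, R_s ~ 2.2 nm).
PROTEIN_D = 1.36e-10


@pytest.fixture(scope="session")
def conical_result():
    """Default conical tubule, 5% slug at 0.10 mg/mL, run to t* = 3."""
    geometry = TubuleGeometry()
    source = SourceSpec(initial_concentration=0.10)
    t_end = 3.0 * geometry.length**2 / PROTEIN_D
    return simulate(geometry, source, PROTEIN_D, [t_end], n_cells=300)


@pytest.fixture(scope="session")
def conical_curve(conical_result):
    return conical_result.pulp_curve


@pytest.fixture(scope="session")
def refit_params(conical_curve):
    """Correlation parameters refit to the conical solver breakthrough curve."""
    return fit_params(conical_curve)
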