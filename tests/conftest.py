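import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from releaseopt import (  # noqa: E402
    Factor,
    ModelTermSet,
    ResponseSurface,
    StudyConfig,
    SyntheticSpec,
    TimePointSpec,
    factorial_design,
    full_second_order,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260214)


@pytest.fixture
def three_factor_config():
    factors = [
        Factor("speed", "rpm", (500, 1000, 1500), 1000, 500),
        Factor("binder", "%", (5, 10, 15), 10, 5),
        Factor("coating", "%", (0, 25, 50), 25, 25),
    ]
    responses = [
        TimePointSpec("y1", "NTB", time=1.0, lsl=20, target=30, usl=40),
        TimePointSpec("y2", "NTB", time=6.0, lsl=50, target=60, usl=70),
    ]
    return StudyConfig(factors=factors, responses=responses)


def dome_surface(label, response, top, apex, curvature):
    """Quadratic dome top - sum c_i (x_i - a_i)^2, expanded to coefficients."""
    k = len(apex)
    terms = full_second_order(k)
    coefs = {str(t): 0.0 for t in terms}
    coefs["1"] = top - sum(c * a * a for c, a in zip(curvature, apex))
    for i, (c, a) in enumerate(zip(curvature, apex)):
        coefs[f"x{i+1}"] = 2 * c * a
        coefs[f"x{i+1}^2"] = -c
    return ResponseSurface(
        terms=terms,
        coefficients=tuple(coefs[s] for s in terms.labels()),
        role="mean",
        label=label,
        response=response,
    )


@pytest.fixture
def dome_truth():
    """Two mean surfaces with a shared dome apex at (0.2, -0.1, 0.4).

    The dome tops (28, 58) sit just below the NTB targets (30, 60), so the
    desirability of each mean stays on its rising side and is maximized
    uniquely at the apex; a truth peaking exactly at the target would make
    the maximizer a level set under any perturbation.
    """
    apex = (0.2, -0.1, 0.4)
    return [
        dome_surface("mu_y1", "y1", 28.0, apex, (4.0, 3.0, 5.0)),
        dome_surface("mu_y2", "y2", 58.0, apex, (5.0, 2.0, 4.0)),
    ], apex


@pytest.fixture
def small_table(dome_truth):
    """27-run, 3-replicate synthetic design from the dome truth, small noise."""
    truth, _ = dome_truth
    design = factorial_design([(-1, 0, 1)] * 3)
    spec = SyntheticSpec(
        mean_surfaces=truth,
        design=design,
        sigma=np.array([[0.09, 0.03], [0.03, 0.09]]),
        m=3,
        labels=("y1", "y2"),
        seed=915,
    )
    from releaseopt import generate_experiment

    return generate_experiment(spec)
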