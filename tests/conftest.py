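import numpy as np
import pytest

from iksgate.params import GatingParameters, RateLaw, default_kcnq1


@pytest.fixture(scope="session")
def baseline_params() -> GatingParameters:
    return default_kcnq1()


def draw_random_params(rng: np.random.Generator) -> GatingParameters:
    """Random positive parameter set for structural (non-phenotype) tests."""

    def law():
        return RateLaw(
            k0=float(10 ** rng.uniform(-0.5, 2.5)), z=float(rng.uniform(-1.5, 1.5))
        )

    def theta():
        return float(10 ** rng.uniform(-0.7, 0.7))

    return GatingParameters(
        k_ri=law(),
        k_ir=law(),
        k_ia=law(),
        k_ai=law(),
        k_co=float(10 ** rng.uniform(0, 2.5)),
        k_oc=float(10 ** rng.uniform(0, 2.5)),
        theta_rc=theta(),
        theta_ic=theta(),
        theta_ac=theta(),
        theta_ro=theta(),
        theta_io=theta(),
        theta_ao=theta(),
    )
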