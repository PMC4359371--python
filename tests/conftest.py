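import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def c6_ring():
    """Noiseless C6 ring on +Z with a 10 A programmed constriction."""
    from ringchannel import RingAssembly, SyntheticRingSpec, generate_ring

    model, truth = generate_ring(SyntheticRingSpec(n_subunits=6, constriction_radius=10.0))
    return RingAssembly(model, tuple("ABCDEF")), truth


@pytest.fixture
def tilted_c6_ring():
    """C6 ring with axis (1,1,1)/sqrt(3) through an off-origin center."""
    from ringchannel import RingAssembly, SyntheticRingSpec, generate_ring

    axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    model, truth = generate_ring(
        SyntheticRingSpec(
            n_subunits=6,
            constriction_radius=10.0,
            axis_direction=axis,
            center=np.array([5.0, -3.0, 12.0]),
        )
    )
    return RingAssembly(model, tuple("ABCDEF")), truth
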