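import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iacskit.phantom import PhantomSpec, build_phantom, optimized_montage, place_montage
from iacskit.solver import assemble_from_contacts, fields_from_potential, solve

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_phantom():
    """Default layered mouse-head phantom at 200 um."""
    return build_phantom(PhantomSpec.default(200.0))


@pytest.fixture(scope="session")
def default_solution(default_phantom):
    """Solved current-flow problem for the deployed montage at 100 uA."""
    montage = optimized_montage()
    placed = place_montage(default_phantom, montage)
    contacts = [(e.role, v) for e, v in placed.items()]
    system = assemble_from_contacts(default_phantom, contacts, montage.current_amplitude_A)
    potential = solve(system)
    fields = fields_from_potential(potential, default_phantom)
    return {
        "phantom": default_phantom,
        "montage": montage,
        "placed": placed,
        "contacts": contacts,
        "system": system,
        "potential": potential,
        "fields": fields,
        "contact_voxels": np.concatenate([v for _, v in contacts]),
    }


@pytest.fixture(scope="session")
def coarse_phantom():
    """Coarse 400 um phantom for fast pipeline/containment checks."""
    return build_phantom(PhantomSpec.default(400.0))
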