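import pytest

from soilcue import io as io_mod
from soilcue.design import build_design
from soilcue.measurement import compute_physiology
from soilcue.simulate import SimulationParams, generate_study


@pytest.fixture(scope="session")
def default_design():
    return build_design()


@pytest.fixture(scope="session")
def noisefree_study():
    """Default study at zero instrument noise (round-trip fixture)."""
    params = SimulationParams(
        seed=42, irms_at_sd=0.0, gc_rel_sd=0.0, eoc_rel_sd=0.0, dna_rel_sd=0.0
    )
    return generate_study(params, noise=False)


@pytest.fixture(scope="session")
def noisy_physiology():
    """Physiology table of a default noisy study, with design attached."""
    study = generate_study(SimulationParams(seed=7))
    phys = compute_physiology(study.bundle)
    return io_mod.attach_design(phys, study.design)
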