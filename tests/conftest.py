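import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_library():
    """A 200-molecule, 10-family synthetic library with fingerprints."""
    from dockpharm import synth, triage

    config = synth.GeneratorConfig(seed=11, n_molecules=200, n_families=10)
    records = synth.gen_library(config)
    fps = {r.id: triage.fingerprint(r.smiles) for r in records}
    return records, fps


@pytest.fixture
def monoexp_profile():
    """Densely sampled monoexponential decay: C(t) = 100 * exp(-0.00693 t)."""
    from dockpharm.invivo import ConcentrationTimeProfile

    times = np.arange(0.0, 1000.0, 10.0)
    conc = 100.0 * np.exp(-0.00693 * times)
    return ConcentrationTimeProfile(
        compartment="plasma", times=times, concentrations=conc, lloq=0.0
    )
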