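import numpy as np
import pytest

from phytoscreen.simulate import (
    WellGeometry,
    phenotype_preset,
    render_side_view,
    simulate_root_system,
)


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced well for fast pipeline tests (same aspect conventions)."""
    return WellGeometry(height_px=120, width_px=40, top_view_px=48)


@pytest.fixture(scope="session")
def control_well():
    """One noise-free control well at default geometry with ground truth."""
    system = simulate_root_system(phenotype_preset("control"), WellGeometry(), seed=42)
    return render_side_view(system, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_control_well():
    system = simulate_root_system(phenotype_preset("control"), WellGeometry(), seed=43)
    return render_side_view(system, noise_sd=0.02, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
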