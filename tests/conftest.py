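import numpy as np
import pytest

from morphomsi import fixtures


@pytest.fixture(scope="session")
def tiny_phantom():
    """One 70 μm-radius core with three follicles; fast to render."""
    follicles = [
        fixtures.Follicle((0.0, 0.0), 20.0, 10.0),
        fixtures.Follicle((-38.0, 18.0), 12.0, 8.0),
        fixtures.Follicle((25.0, -30.0), 13.0, 9.0),
    ]
    core = fixtures.CorePhantom((100.0, 100.0), 70.0, "PTC", follicles)
    return fixtures.FixturePhantom(cores=[core], mz_range=(700.0, 760.0), seed=7)


@pytest.fixture(scope="session")
def tiny_scene(tiny_phantom):
    return fixtures.render_he_image(tiny_phantom)


@pytest.fixture(scope="session")
def tiny_model():
    return fixtures.SpectrumModel(
        peptide_peaks={"PTC": [(722.40, 40.0)]},
        shared_peptide_peaks=[(745.60, 30.0)],
        reference_peaks=[(709.30, 35.0)],
        interferent_peaks=[(712.20, 8.0, 4.0)],
        trypsin_peaks=[(733.80, 12.0)],
    )


@pytest.fixture(scope="session")
def tiny_cube(tiny_phantom, tiny_scene, tiny_model):
    ds, gt = fixtures.render_msi_cube(tiny_phantom, tiny_model, tiny_scene)
    return ds, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
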