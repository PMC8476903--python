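import numpy as np
import pytest

from baods.phantom import Ellipsoid, PhantomConfig, generate_case


@pytest.fixture(scope="session")
def small_case():
    """A coarse default phantom (8 mm voxels) shared across tests."""
    return generate_case(PhantomConfig(shape=(48, 48, 24), spacing=(8, 8, 8)))


def symmetric_config(noise_sd: float = 0.0, seed: int = 0) -> PhantomConfig:
    """Rotationally symmetric phantom: spherical body and centred tumor,
    OARs shrunk to (empty-mask) points so no angle is preferred."""
    organs = {
        "body": Ellipsoid((0, 0, 0), (90.0, 90.0, 90.0)),
        "TLV": Ellipsoid((0, 0, 0), (40.0, 40.0, 40.0)),
        "duodenum": Ellipsoid((0, 0, -70), (0.5, 0.5, 0.5)),
        "stomach": Ellipsoid((0, 0, -60), (0.5, 0.5, 0.5)),
        "esophagus": Ellipsoid((0, 0, 60), (0.5, 0.5, 0.5)),
        "heart": Ellipsoid((0, 0, 70), (0.5, 0.5, 0.5)),
        "spleen": Ellipsoid((0, 0, 50), (0.5, 0.5, 0.5)),
    }
    return PhantomConfig(
        shape=(48, 48, 48),
        spacing=(4.0, 4.0, 4.0),
        organs=organs,
        tumor_offset=(0.0, 0.0, 0.0),
        tumor_semi_axes=(15.0, 15.0, 15.0),
        noise_sd=noise_sd,
        seed=seed,
        case_id="symmetric",
    )


@pytest.fixture(scope="session")
def symmetric_case():
    return generate_case(symmetric_config())
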