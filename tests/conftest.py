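import numpy as np
import pytest

from msfnet.data import generate_synthetic_dataset, generate_synthetic_manifest


@pytest.fixture(scope="session")
def small_manifest():
    """In-memory 5-class synthetic set, 10 images/class at 32x32."""
    return generate_synthetic_manifest(n_per_class=10, image_size=(32, 32), seed=11)


@pytest.fixture(scope="session")
def image_folder(tmp_path_factory):
    """Materialized 5-class synthetic folder, 4 images/class at 48x48."""
    root = tmp_path_factory.mktemp("synth")
    manifest = generate_synthetic_dataset(
        str(root), n_per_class=4, image_size=(48, 48), seed=3
    )
    return str(root), manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
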