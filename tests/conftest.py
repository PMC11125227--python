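import numpy as np
import pytest

from kpfuse import JointCatalog, KeypointSequence


@pytest.fixture(scope="session")
def catalog():
    return JointCatalog.default()


def build_sequence(
    coords,
    valid=None,
    rate=30.0,
    source="reference",
    unit="m",
    t0=0.0,
):
    """Sequence from an (n, j, 3) array over the default 12-joint catalog."""
    coords = np.asarray(coords, dtype=float)
    n, j, _ = coords.shape
    names = JointCatalog.default().names[:j]
    if valid is None:
        valid = np.ones((n, j), dtype=bool)
    coords = coords.copy()
    coords[~np.asarray(valid, dtype=bool)] = np.nan
    return KeypointSequence(
        joints=names,
        frame_index=np.arange(n),
        timestamps=t0 + np.arange(n) / rate,
        coords=coords,
        valid=np.asarray(valid, dtype=bool),
        rate=rate,
        source=source,
        unit=unit,
    )


@pytest.fixture
def random_sequence(catalog):
    rng = np.random.default_rng(42)
    coords = rng.normal(size=(5, 12, 3))
    valid = rng.random((5, 12)) > 0.1
    return build_sequence(coords, valid=valid)
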