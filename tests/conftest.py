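import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xlvalidate.structure_io import ResidueRecord, Structure

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def structure_from_coords(coords, chain_id="A", plddt=None, name="TEST", start=1,
                          aa="A"):
    """Build a single-chain structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    records = [
        ResidueRecord(
            chain_id=chain_id,
            residue_index=start + k,
            aa_code=aa,
            ca_xyz=tuple(xyz),
            plddt=None if plddt is None else float(np.atleast_1d(plddt)[k % len(np.atleast_1d(plddt))]),
        )
        for k, xyz in enumerate(coords)
    ]
    return Structure(name=name, chains={chain_id: records})


@pytest.fixture
def make_structure_from_coords():
    return structure_from_coords


@pytest.fixture
def random_walk_structure():
    """50-residue random-walk C-alpha trace (fixed seed)."""
    rng = np.random.default_rng(77)
    steps = rng.normal(size=(50, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.cumsum(3.8 * steps, axis=0)
    return structure_from_coords(coords, name="WALK")
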