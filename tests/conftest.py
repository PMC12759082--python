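import numpy as np
import pytest

from rgplineage import (
    CloneSizeModel,
    DEFAULT_TRANSITION_MATRIX,
    simulate_lineage,
)
from rgplineage.types import CellRecord, Clone


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_clone(intensities, clone_id="c", positions=None):
    """Build a clone from raw intensities (and optional positions)."""

    cells = []
    for i, intensity in enumerate(intensities):
        cells.append(
            CellRecord(
                clone_id=clone_id,
                cell_id=f"{clone_id}.n{i + 1}",
                intensity=float(intensity),
                position=None if positions is None else np.asarray(positions[i], float),
            )
        )
    return Clone(clone_id=clone_id, cells=cells)


@pytest.fixture
def small_trees(rng):
    """Twenty small simulated lineages (<= 10 neurons)."""

    return [
        simulate_lineage(
            CloneSizeModel(), DEFAULT_TRANSITION_MATRIX, rng, max_size=10,
            clone_id=f"t{i}",
        )
        for i in range(20)
    ]
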