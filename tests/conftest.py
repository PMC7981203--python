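import numpy as np
import pytest

from sizeflm.brood_data import BroodCell, StageCode
from sizeflm.vital_rates import SizeGrid, WorkerRecord


@pytest.fixture
def simple_grid():
    """14 equal bins over the 2.0-4.8 mm span range."""
    return SizeGrid(np.linspace(2.0, 4.8, 15))


def make_cell(cell_id, obs, colony="c1", clump="k1"):
    return BroodCell(
        cell_id=cell_id,
        colony_id=colony,
        clump_id=clump,
        observations=[(d, StageCode(s)) for d, s in obs],
    )


def make_worker(worker_id, span, presence, colony="c1", first=None):
    presence = set(presence)
    return WorkerRecord(
        worker_id=worker_id,
        colony_id=colony,
        first_capture_day=min(presence) if first is None else first,
        it_span=span,
        wet_weight=300.0,
        presence=presence,
    )
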