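import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from traitwebs.data import InteractionRecord, SpecimenMeasurement


def random_count_matrix(rng, max_rows=6, max_cols=6, max_count=8, min_rows=2, min_cols=2):
    """Random non-negative integer matrix with no zero row or column."""
    while True:
        p = rng.integers(min_rows, max_rows + 1)
        a = rng.integers(min_cols, max_cols + 1)
        M = rng.integers(0, max_count + 1, size=(p, a))
        if (M.sum(axis=1) > 0).all() and (M.sum(axis=0) > 0).all():
            return M.astype(np.int64)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_record():
    def _make(rid, bee="Bee_01", plant="Plant_01", itd=2.0, fds=10.0,
              itype="nectar", year=2011):
        return InteractionRecord(rid, bee, plant, itd, fds, itype, year)

    return _make


@pytest.fixture
def tiny_dataset(make_record):
    from traitwebs.data import CommunityDataset

    records = [
        make_record("R1", bee="Bee_01", plant="Plant_01", itd=2.0, fds=10.0),
        make_record("R2", bee="Bee_02", plant="Plant_01", itd=3.0, fds=12.0),
        make_record("R3", bee="Bee_02", plant="Plant_02", itd=3.1, fds=20.0),
    ]
    specimens = [
        SpecimenMeasurement("bee", "Bee_01", 2.0, 3.0),
        SpecimenMeasurement("bee", "Bee_01", 2.5, 3.6),
        SpecimenMeasurement("bee", "Bee_02", 3.0, 4.4),
        SpecimenMeasurement("plant", "Plant_02", 18.0, 4.0),
        SpecimenMeasurement("plant", "Plant_02", 22.0, 5.0),
    ]
    return CommunityDataset(records, specimens, immeasurable_plant_species={"Plant_01"})
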