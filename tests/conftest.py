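import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from sectorloh.model import Genotype, GenotypeTrack, MarkerMap, SectorPair

_CODE = {
    "h": Genotype.HET,
    "W": Genotype.HOM_W,
    "Y": Genotype.HOM_Y,
    ".": Genotype.UNCALLED,
    "L": Genotype.HEMIZYGOUS_LOSS,
}


def states_from_string(s: str) -> np.ndarray:
    """Compact genotype-track notation: h=HET W=HOM_W Y=HOM_Y .=UNCALLED."""
    return np.asarray([int(_CODE[c]) for c in s], dtype=np.int8)


def make_track(s, sector: str = "red") -> GenotypeTrack:
    states = states_from_string(s) if isinstance(s, str) else np.asarray(s, np.int8)
    n = len(states)
    return GenotypeTrack(sector, states, np.zeros(n), np.zeros(n, dtype=bool))


def make_pair(red, white, positions=None, colony_id="c0") -> SectorPair:
    rt = make_track(red, "red")
    wt = make_track(white, "white")
    n = len(rt)
    if positions is None:
        positions = 1000 + 500 * np.arange(n)
    ids = np.asarray([f"m{i}" for i in range(n)], dtype=object)
    mm = MarkerMap("chrIV", ids, np.asarray(positions, np.int64))
    return SectorPair(colony_id, rt, wt, mm)


@pytest.fixture
def small_map() -> MarkerMap:
    pos = 1000 + 500 * np.arange(40)
    ids = np.asarray([f"m{i}" for i in range(40)], dtype=object)
    return MarkerMap("chrIV", ids, pos)
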