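"""Shared domain types for the sectored-colony LOH mapping pipeline.

Coordinates are 1-based inclusive SGD positions throughout; BED input is
converted at the I/O boundary.  The experimental unit is a red/white sectored
colony: the two sectors are the two daughter lineages of a cell that underwent
a reciprocal mitotic crossover at plating, so together they expose all four
chromatids of the G2 cell in which the exchange happened.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# enumerations


class Genotype(enum.IntEnum):
    """Per-marker zygosity call for one sector sample."""

    HET = 0
    HOM_W = 1
    HOM_Y = 2
    UNCALLED = 3
    HEMIZYGOUS_LOSS = 4


class ProfileLabel(enum.IntEnum):
    """Combined four-chromatid state at one marker (red + white sectors).

    The integer values of HET22..Y40 equal the number of W303a (W) alleles
    carried by the four chromatids only incidentally; use ``W_COUNT``.
    """

    HET22 = 0      # both sectors heterozygous: 2 W + 2 Y
    RECIP22 = 1    # one sector HOM_W, the other HOM_Y: reciprocal LOH
    W31 = 2        # 3 W : 1 Y  (one sector HOM_W, the other HET)
    Y31 = 3        # 1 W : 3 Y
    W40 = 4        # 4 W : 0 Y  (both sectors HOM_W)
    Y40 = 5        # 0 W : 4 Y
    UNKNOWN = 6    # uncalled / hemizygous in either sector


W_COUNT = {
    ProfileLabel.HET22: 2,
    ProfileLabel.RECIP22: 2,
    ProfileLabel.W31: 3,
    ProfileLabel.Y31: 1,
    ProfileLabel.W40: 4,
    ProfileLabel.Y40: 0,
}


class TractClass(str, enum.Enum):
    """Conversion-tract classes.

    3:1 tracts arise from repair of a single broken chromatid (S/G2 lesion);
    4:0 tracts require both sister chromatids converted, i.e. a lesion
    replicated before repair (G1); hybrids reflect unequal processing of the
    two broken sisters.
    """

    NONE = "NONE"
    SIMPLE_31 = "SIMPLE_31"
    SIMPLE_40 = "SIMPLE_40"
    HYBRID_4031 = "HYBRID_4031"
    HYBRID_3140 = "HYBRID_3140"
    HYBRID_314031 = "HYBRID_314031"
    COMPLEX = "COMPLEX"


HYBRID_CLASSES = frozenset(
    {TractClass.HYBRID_4031, TractClass.HYBRID_3140, TractClass.HYBRID_314031}
)
SIMPLE_CLASSES = frozenset(
    {TractClass.SIMPLE_31, TractClass.SIMPLE_40} | HYBRID_CLASSES
)


class Timing(str, enum.Enum):
    G1 = "G1"
    G2 = "G2"


class Homolog(str, enum.Enum):
    W = "W"  # W303a-derived
    Y = "Y"  # YJM789-derived


class Donor(str, enum.Enum):
    W = "W"
    Y = "Y"
    AMBIGUOUS = "AMBIGUOUS"


# ---------------------------------------------------------------------------
# containers


@dataclass
class MarkerMap:
    """Ordered SNP marker coordinates on one chromosome arm."""

    chromosome: str
    ids: np.ndarray          # dtype=object / str
    positions: np.ndarray    # int64, 1-based, strictly increasing

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.ids.shape != self.positions.shape:
            raise ValueError("ids and positions must have equal length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("marker ids must be unique")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])


@dataclass
class RatioTrack:
    """Allele-specific normalized hybridization ratios for one sector.

    ``w`` and ``y`` are the experimental/reference ratios of the probes
    matching the W303a and YJM789 allele respectively, strand-averaged.
    Heterozygous markers sit near (1, 1); homozygosity raises the retained
    allele to ~1.6 and drops the lost one to ~0.3.
    """

    sector: str              # "red" or "white"
    w: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.w.shape != self.y.shape:
            raise ValueError("w and y ratio arrays must have equal length")
        for arr in (self.w, self.y):
            if np.any(arr[~np.isnan(arr)] < 0):
                raise ValueError("hybridization ratios must be >= 0")

    def __len__(self) -> int:
        return len(self.w)


@dataclass
class GenotypeTrack:
    """Per-marker zygosity calls with distance-to-centroid confidence."""

    sector: str
    states: np.ndarray        # int8 of Genotype values
    confidence: np.ndarray    # distance to nearest centroid (np.inf for NaN)
    low_confidence: np.ndarray  # bool: flagged singleton calls (min_run rule)

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class SectorPair:
    """The red/white daughter pair of one sectored colony."""

    colony_id: str
    red: GenotypeTrack
    white: GenotypeTrack
    marker_map: MarkerMap

    def __post_init__(self) -> None:
        if not (len(self.red) == len(self.white) == len(self.marker_map)):
            raise ValueError(
                f"colony {self.colony_id}: sector tracks and marker map "
                "must have equal length"
            )


@dataclass
class ChromatidProfile:
    """Derived four-chromatid allele counts and labels per marker."""

    w_count: np.ndarray   # int8, -1 where unknown
    labels: np.ndarray    # int8 of ProfileLabel values

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TractSegment:
    label: str               # "W31", "Y31", "W40", "Y40", "22", "R22"
    start_bp: int            # first converted marker of the run
    end_bp: int              # last converted marker of the run
    flank_left: tuple[int, int]   # (outer unconverted SNP, first SNP of run)
    flank_right: tuple[int, int]  # (last SNP of run, outer unconverted SNP)
    n_markers: int


@dataclass
class ConversionTract:
    """A reconstructed, classified gene-conversion tract."""

    segments: list[TractSegment]
    tract_class: TractClass
    signature: str                      # canonical label sequence, e.g. "W31-22-W31"
    donor: Donor
    initiating: Donor                   # the non-donor (broken) homolog
    timing: Timing
    length_min: int
    length_mid: int
    length_max: int
    dsb_region: tuple[int, int]
    span: tuple[int, int]               # outermost converted markers
    marker_range: tuple[int, int]       # marker indices (inclusive)
    ambiguous: bool = False             # >50% UNKNOWN in the candidate region
    qc_flags: list[str] = field(default_factory=list)

    @property
    def terminus_windows(self) -> list[tuple[int, int]]:
        """The two het<->hom transition intervals bounding the tract."""
        if not self.segments:
            return []
        return [self.segments[0].flank_left, self.segments[-1].flank_right]


@dataclass
class CrossoverEvent:
    """A reciprocal-crossover event detected in one sectored colony."""

    colony_id: str
    red_transition: tuple[int, int]     # flanking-SNP coordinates
    white_transition: tuple[int, int]
    point_bp: int
    tract: Optional[ConversionTract]
    multiplicity: int = 1               # >1 when the colony has several crossovers
    qc_flags: list[str] = field(default_factory=list)

    @property
    def tract_class(self) -> TractClass:
        return self.tract.tract_class if self.tract is not None else TractClass.NONE

    @property
    def timing(self) -> Optional[Timing]:
        return self.tract.timing if self.tract is not None else None


@dataclass
class ElementTrack:
    """Intervals of one chromosome-element class (Ty, LTR, tRNA, ...)."""

    name: str
    intervals: np.ndarray    # (n, 2) int64, 1-based inclusive, sorted, merged
    homolog: str = "both"    # W / Y / both

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if np.any(iv[:, 0] > iv[:, 1]):
            raise ValueError(f"element class {self.name}: start > end")
        order = np.argsort(iv[:, 0], kind="stable")
        iv = iv[order]
        merged: list[list[int]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], int(e))
            else:
                merged.append([int(s), int(e)])
        self.intervals = np.asarray(merged, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.intervals)


def profile_label_name(code: int) -> str:
    """Short segment-label string used in signatures and event tables."""
    lab = ProfileLabel(code)
    if lab is ProfileLabel.HET22:
        return "22"
    if lab is ProfileLabel.RECIP22:
        return "R22"
    return lab.name
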