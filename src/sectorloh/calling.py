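"""Genotype calling from allele-specific hybridization ratios.

A marker is called by nearest-centroid assignment in the (w, y) ratio plane
against the three expected levels — heterozygous (1.0, 1.0), homozygous-W
(1.6, 0.3), homozygous-Y (0.3, 1.6) — with a rejection radius beyond which a
marker is UNCALLED.  Ties break toward UNCALLED.  A separate heuristic flags
markers consistent with hemizygous loss (one homolog deleted), which are
excluded from tract arithmetic and reported via arm-level dosage QC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Genotype, GenotypeTrack, RatioTrack


@dataclass
class CallerConfig:
    centroids: dict = field(
        default_factory=lambda: {
            Genotype.HET: (1.0, 1.0),
            Genotype.HOM_W: (1.6, 0.3),
            Genotype.HOM_Y: (0.3, 1.6),
        }
    )
    max_distance: float = 0.45
    min_run: int = 2
    hemizygous_low: float = 0.55
    hemizygous_high: float = 1.1   # the retained allele stays near or below 1

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        pts = list(self.centroids.values())
        if len({tuple(p) for p in pts}) != len(pts):
            raise ValueError("centroids must be distinct")


DEFAULT_CALLER = CallerConfig()


def call_marker(w_ratio: float, y_ratio: float, config: CallerConfig = DEFAULT_CALLER) -> Genotype:
    """Call a single marker; NaN input yields UNCALLED, never an exception."""
    states, dist = _distances(np.asarray([w_ratio], float), np.asarray([y_ratio], float), config)
    return Genotype(int(states[0]))


def _distances(w: np.ndarray, y: np.ndarray, config: CallerConfig):
    """Vectorized nearest-centroid assignment. Returns (states, distances)."""
    genos = list(config.centroids.keys())
    cents = np.asarray([config.centroids[g] for g in genos], float)  # (3, 2)
    pts = np.stack([w, y], axis=1)                                   # (n, 2)
    nan = np.isnan(w) | np.isnan(y)
    safe = np.where(nan[:, None], 0.0, pts)
    d = np.sqrt(((safe[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2))  # (n, 3)
    nearest = np.argmin(d, axis=1)
    dmin = d[np.arange(len(w)), nearest]
    states = np.asarray([int(genos[i]) for i in nearest], dtype=np.int8)

    reject = dmin > config.max_distance
    dsort = np.sort(d, axis=1)
    reject |= dsort[:, 0] == dsort[:, 1]  # equidistant: break toward UNCALLED
    states[reject] = int(Genotype.UNCALLED)
    # hemizygous-loss heuristic: one allele essentially absent, the other at
    # single-copy level, and nothing within the rejection radius
    lo, hi = config.hemizygous_low, config.hemizygous_high
    hemi = reject & (np.minimum(w, y) < lo) & (np.maximum(w, y) <= hi)
    hemi &= ~nan
    states[hemi] = int(Genotype.HEMIZYGOUS_LOSS)

    states[nan] = int(Genotype.UNCALLED)
    dmin = np.where(nan, np.inf, dmin)
    return states, dmin


def call_track(ratio_track: RatioTrack, config: CallerConfig = DEFAULT_CALLER) -> GenotypeTrack:
    """Call every marker of a sector and flag suspect singleton calls.

    With ``min_run=2``, an isolated single-marker state whose two nearest
    called neighbors agree on a different state is kept but marked
    low-confidence: array resolution is ~500 bp, so single-SNP conversions
    are possible but suspect.
    """
    states, dist = _distances(ratio_track.w, ratio_track.y, config)
    low = np.zeros(len(states), dtype=bool)
    if config.min_run >= 2:
        called = np.flatnonzero(
            (states != Genotype.UNCALLED) & (states != Genotype.HEMIZYGOUS_LOSS)
        )
        s = states[called]
        if len(s) >= 3:
            mid = (s[1:-1] != s[:-2]) & (s[1:-1] != s[2:]) & (s[:-2] == s[2:])
            low[called[1:-1][mid]] = True
    return GenotypeTrack(ratio_track.sector, states, dist, low)


def segment_track(track: GenotypeTrack) -> list[tuple[Genotype, int, int]]:
    """Maximal runs of equal called state, (state, start index, end index).

    UNCALLED (and hemizygous-flagged) markers are absorbed into the enclosing
    run without splitting it; leading uncallable markers attach to the first
    called run.  Concatenating the runs covers every marker exactly once.
    """
    states = np.asarray(track.states)
    n = len(states)
    if n == 0:
        return []
    absorb = (states == Genotype.UNCALLED) | (states == Genotype.HEMIZYGOUS_LOSS)
    called_idx = np.flatnonzero(~absorb)
    if len(called_idx) == 0:
        return [(Genotype.UNCALLED, 0, n - 1)]
    # assign each marker the state of the nearest preceding called marker
    # (leading uncalled markers take the first called state)
    eff = np.empty(n, dtype=np.int8)
    pos = np.searchsorted(called_idx, np.arange(n), side="right") - 1
    pos = np.clip(pos, 0, len(called_idx) - 1)
    eff = states[called_idx[pos]]
    change = np.flatnonzero(np.diff(eff)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [n - 1]])
    return [(Genotype(int(eff[s])), int(s), int(e)) for s, e in zip(starts, ends)]


@dataclass
class DosageQC:
    status: str                       # "euploid" or "flagged"
    mean_dosage: float
    loss_regions: list[tuple[int, int]]   # bp intervals flagged HEMIZYGOUS_LOSS


def arm_dosage_qc(
    ratio_track: RatioTrack,
    positions: np.ndarray | None = None,
    tolerance: float = 0.2,
    region_threshold: float = 1.7,
    min_region_markers: int = 20,
) -> DosageQC:
    """Arm-wide copy-number sanity check.

    The sum of the two allele ratios should average 2.0 on a euploid
    heterozygous diploid arm; a departure beyond ``tolerance`` flags the
    whole arm (aneuploidy / normalization failure).  Contiguous runs of
    markers whose smoothed dosage falls below ``region_threshold`` are
    reported as candidate hemizygous-loss regions, e.g. the ~100-kb deletion
    between inverted Ty pairs seen in one sector of the original dataset.
    """
    dosage = ratio_track.w + ratio_track.y
    mean = float(np.nanmean(dosage))
    status = "euploid" if abs(mean - 2.0) <= tolerance else "flagged"

    # rolling-median smoothing to suppress per-marker noise
    k = 11
    n = len(dosage)
    regions: list[tuple[int, int]] = []
    if n >= min_region_markers:
        pad = k // 2
        padded = np.pad(dosage, pad, mode="edge")
        windows = np.lib.stride_tricks.sliding_window_view(padded, k)
        smooth = np.nanmedian(windows, axis=1)
        low = smooth < region_threshold
        change = np.flatnonzero(np.diff(low.astype(np.int8)))
        bounds = np.concatenate([[0], change + 1, [n]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            if low[s] and (e - s) >= min_region_markers:
                if positions is not None:
                    regions.append((int(positions[s]), int(positions[e - 1])))
                else:
                    regions.append((int(s), int(e - 1)))
    if regions:
        status = "flagged"
    return DosageQC(status, mean, regions)


def calling_accuracy(true_states: np.ndarray, track: GenotypeTrack) -> float:
    """Fraction of markers whose call matches the simulated genotype."""
    true_states = np.asarray(true_states)
    if len(true_states) == 0:
        return float("nan")
    return float(np.mean(np.asarray(track.states) == true_states))
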