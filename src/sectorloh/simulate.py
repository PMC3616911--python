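"""Synthetic sectored-colony datasets with known ground truth.

The generator emulates the structure of the study system: a heterozygous
diploid arm of ~1.1 Mb (coordinates 449–1520 kb) carrying ~2300 SNP markers,
on which spontaneous reciprocal crossovers with associated gene-conversion
tracts are placed.  Each simulated event produces the four chromatid allele
tracks of the G2 cell, the red/white daughter genotypes, and noisy
allele-specific hybridization ratio tracks (het ~1.0, retained homozygous
allele ~1.6, lost allele ~0.3).

Timing model: a G2 lesion breaks one chromatid, whose repair off the homolog
yields a 3:1 tract; a G1 lesion is replicated into two broken sisters whose
independent repair yields 4:0 segments where both conversions overlap and
3:1 segments where only one does.  The observable tract span is drawn
log-normal at the configured median (the medians reported for real data are
medians of observed tracts) and partitioned into the two sister extents.

The truth record stores both the mechanistic event (timing, lesion position,
extents) and the *observable* class — the class an ideal noise-free observer
of the chromatid states at the marker positions would assign.  The two can
differ: segments narrower than the marker spacing are invisible, and a G1
event whose sister tracts share no marker is indistinguishable from G2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .model import Genotype, MarkerMap, RatioTrack, TractClass
from . import tracts as _tracts


@dataclass
class Hotspot:
    center: int
    weight: float
    homolog: Optional[str] = None   # "W" / "Y" restriction, None = both
    timing: Optional[str] = None    # "G1" / "G2" restriction, None = both
    width: int = 10_000             # half-width of the triangular kernel


def default_hotspots() -> list[Hotspot]:
    """Inverted-Ty-pair hotspots at 872 and 981 kb: G1- and W-specific."""
    return [
        Hotspot(872_000, 0.08, homolog="W", timing="G1"),
        Hotspot(981_000, 0.08, homolog="W", timing="G1"),
    ]


@dataclass
class SimulationConfig:
    arm_start: int = 449_000
    arm_end: int = 1_520_000
    n_markers: int = 2300
    marker_jitter: int = 150
    p_G1: float = 2 / 3
    p_no_conversion: float = 18 / 139
    p_complex: float = 39 / 139
    hotspots: list[Hotspot] = field(default_factory=default_hotspots)
    uniform_weight: float = 0.84
    tract_median_G1: float = 14_800.0
    tract_median_G2: float = 4_700.0
    sigma_log: float = 1.0
    ratio_levels: tuple[float, float, float] = (1.0, 1.6, 0.3)
    noise_sd: float = 0.1
    seed: int = 0
    # crossovers land proximal to the selectable markers near the telomere
    xover_margin: int = 10_000
    # G1 sister-extent fractions: full with p_full, else U(f_min, 1)
    f_min: float = 0.3
    p_full_extent: float = 0.25
    patch_len: tuple[int, int] = (200, 2000)

    def __post_init__(self) -> None:
        if self.arm_start >= self.arm_end:
            raise ValueError("arm_start must be < arm_end")
        if self.n_markers < 2:
            raise ValueError("n_markers must be >= 2")
        for name in ("p_G1", "p_no_conversion", "p_complex"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.tract_median_G1, self.tract_median_G2) <= 0:
            raise ValueError("tract-length medians must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TruthRecord:
    event_id: str
    category: str          # NONE / SIMPLE / COMPLEX (generator's draw)
    initiating: str        # homolog carrying the lesion (W / Y)
    donor: str             # the intact template homolog
    timing: str            # mechanistic cell-cycle stage of the lesion
    dsb_bp: int
    xover_bp: int
    span_start: int        # observable tract span (union of extents); dsb for NONE
    span_end: int
    extent_co_start: int   # conversion on the crossover chromatid
    extent_co_end: int
    extent_other_start: int  # second sister (G1 only; -1 otherwise)
    extent_other_end: int
    n_patches: int
    obs_class: str         # marker-resolution observable class
    obs_signature: str
    obs_timing: str        # 4:0-presence rule applied to the observable tract
    obs_donor: str


def simulate_marker_map(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> MarkerMap:
    """Place n_markers SNPs on the arm: an even grid plus positional jitter."""
    n = config.n_markers
    span = config.arm_end - config.arm_start
    if n > span + 1:
        raise ValueError("n_markers exceeds the number of distinct bp positions")
    grid = np.floor(np.linspace(config.arm_start, config.arm_end, n)).astype(np.int64)
    if config.marker_jitter > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        jit = rng.integers(-config.marker_jitter, config.marker_jitter + 1, size=n)
        pos = np.clip(grid + jit, config.arm_start, config.arm_end)
        pos.sort()
        # resolve collisions while staying inside the arm
        for i in range(1, n):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        if pos[-1] > config.arm_end:
            raise ValueError("jittered markers exceed the arm; reduce jitter")
    else:
        pos = grid
    ids = np.asarray([f"snp{p}" for p in pos], dtype=object)
    return MarkerMap(chromosome="chrIV", ids=ids, positions=pos)


# ---------------------------------------------------------------------------
# event simulation


def _draw_lesion(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, str, str]:
    """Draw (dsb position, initiating homolog, timing).

    Timing and homolog are drawn first; the lesion position then comes from
    the mixture of the uniform background and the hotspots *compatible* with
    that timing/homolog, so restricted hotspots (e.g. the G1/W-specific
    inverted-Ty pairs) concentrate only their own event class.
    """
    timing = "G1" if rng.random() < config.p_G1 else "G2"
    homolog = "W" if rng.random() < 0.5 else "Y"
    comps: list[tuple[float, Optional[Hotspot]]] = []
    if config.uniform_weight > 0:
        comps.append((config.uniform_weight, None))
    for hs in config.hotspots:
        if hs.homolog is not None and hs.homolog != homolog:
            continue
        if hs.timing is not None and hs.timing != timing:
            continue
        if hs.weight > 0:
            comps.append((hs.weight, hs))
    total = sum(w for w, _ in comps)
    if total <= 0:
        raise ValueError(
            "hotspot weights sum to 0 with the uniform component disabled"
        )
    u = rng.random() * total
    acc = 0.0
    chosen: Optional[Hotspot] = None
    for w, hs in comps:
        acc += w
        if u <= acc:
            chosen = hs
            break
    hi = config.arm_end - config.xover_margin
    if chosen is None:
        dsb = int(rng.uniform(config.arm_start, hi))
    else:
        dsb = int(rng.triangular(chosen.center - chosen.width, chosen.center,
                                 chosen.center + chosen.width))
        dsb = int(np.clip(dsb, config.arm_start, hi))
    return dsb, homolog, timing


def _lognormal_length(median: float, sigma: float, rng: np.random.Generator) -> int:
    return max(1, int(round(median * np.exp(sigma * rng.standard_normal()))))


def _extent_fraction(config: SimulationConfig, rng: np.random.Generator) -> float:
    if rng.random() < config.p_full_extent:
        return 1.0
    return float(rng.uniform(config.f_min, 1.0))


def simulate_event(
    config: SimulationConfig,
    rng: np.random.Generator,
    marker_map: MarkerMap,
    event_id: str = "ev0",
    force_category: Optional[str] = None,
    force_patches: Optional[int] = None,
    force_length: Optional[int] = None,
):
    """Simulate one crossover event; returns (TruthRecord, chromatid tracks).

    The chromatid tracks are a (4, n_markers) int8 array of alleles
    (0 = W303a, 1 = YJM789) ordered (red_a, red_b, white_a, white_b).
    """
    dsb, homolog, timing = _draw_lesion(config, rng)

    if force_category is not None:
        category = force_category
    else:
        if rng.random() < config.p_no_conversion:
            category = "NONE"
        else:
            rem = 1.0 - config.p_no_conversion
            p_cx = config.p_complex / rem if rem > 0 else 0.0
            category = "COMPLEX" if rng.random() < p_cx else "SIMPLE"

    lo_arm = config.arm_start
    hi_xover = config.arm_end - config.xover_margin

    if category == "NONE":
        span = (dsb, dsb)
        extent_co = (dsb, dsb - 1)      # empty
        extent_other = None
        xover = dsb
        length = 0
    else:
        median = config.tract_median_G1 if timing == "G1" else config.tract_median_G2
        length = force_length if force_length is not None else _lognormal_length(
            median, config.sigma_log, rng
        )
        if timing == "G2":
            u = rng.random()
            span_start = dsb - int(u * length)
            span_end = span_start + length
            f_co, f_oth = 1.0, None
        else:
            f_co = _extent_fraction(config, rng)
            f_oth = _extent_fraction(config, rng)
            while f_co + f_oth < 1.0:
                f_co = _extent_fraction(config, rng)
                f_oth = _extent_fraction(config, rng)
            ov = (f_co + f_oth - 1.0) * length
            u = rng.random()
            span_start = dsb - int((1.0 - f_co) * length + u * ov)
            span_end = span_start + length
        # keep the crossover proximal to the selection markers
        if span_end > hi_xover:
            shift = span_end - hi_xover
            span_start -= shift
            span_end -= shift
            dsb -= shift
        if span_start < lo_arm:  # truncate at the centromere-proximal edge
            span_start = lo_arm
            dsb = max(dsb, lo_arm)
        xover = span_end
        extent_co = (max(span_start, span_end - int(f_co * length)), span_end)
        if timing == "G1":
            extent_other = (span_start, min(span_end, span_start + int(f_oth * length)))
        else:
            extent_other = None
        span = (span_start, span_end)

    patches: list[tuple[int, int]] = []
    if category == "COMPLEX":
        n_p = int(force_patches) if force_patches is not None else int(rng.integers(1, 3))
        span_len = span[1] - span[0]
        for _ in range(n_p):
            plen = int(rng.uniform(*config.patch_len))
            if span_len <= plen + 10:
                continue
            ps = int(rng.uniform(span[0], span[1] - plen))
            patches.append((ps, ps + plen))

    tracks = _assemble_chromatids(
        marker_map.positions, homolog, timing, xover, extent_co, extent_other, patches
    )

    donor = "W" if homolog == "Y" else "Y"
    truth = TruthRecord(
        event_id=event_id,
        category=category,
        initiating=homolog,
        donor=donor,
        timing=timing,
        dsb_bp=int(dsb),
        xover_bp=int(xover),
        span_start=int(span[0]),
        span_end=int(span[1]),
        extent_co_start=int(extent_co[0]),
        extent_co_end=int(extent_co[1]),
        extent_other_start=int(extent_other[0]) if extent_other else -1,
        extent_other_end=int(extent_other[1]) if extent_other else -1,
        n_patches=len(patches),
        obs_class="", obs_signature="", obs_timing="", obs_donor="",
    )
    _fill_observable(truth, tracks, marker_map)
    return truth, tracks


def _assemble_chromatids(
    positions: np.ndarray,
    initiating: str,
    timing: str,
    xover: int,
    extent_co: tuple[int, int],
    extent_other: Optional[tuple[int, int]],
    patches: list[tuple[int, int]],
) -> np.ndarray:
    """Build the four chromatid allele tracks (0 = W, 1 = Y).

    The broken (initiating) homolog is the recipient: its chromatid(s) copy
    donor alleles over the conversion extents.  The crossover swaps the
    segments distal to ``xover`` between the recombining chromatid pair, and
    the daughters segregate so that the red sector is homozygous W303a
    distal to the exchange (loss of the SUP4-o-bearing YJM789 arm).
    """
    n = len(positions)
    donor_allele = 0 if initiating == "Y" else 1
    recip_allele = 1 - donor_allele

    intact_a = np.full(n, donor_allele, dtype=np.int8)   # donor homolog, sister 1
    intact_b = np.full(n, donor_allele, dtype=np.int8)   # donor homolog, sister 2
    broken_co = np.full(n, recip_allele, dtype=np.int8)  # recipient, crossover sister
    broken_oth = np.full(n, recip_allele, dtype=np.int8)

    def _mask(iv):
        return (positions >= iv[0]) & (positions <= iv[1])

    if extent_co[1] >= extent_co[0]:
        broken_co[_mask(extent_co)] = donor_allele
    if extent_other is not None and extent_other[1] >= extent_other[0]:
        broken_oth[_mask(extent_other)] = donor_allele
    for iv in patches:  # unrepaired heteroduplex on the crossover chromatid
        broken_co[_mask(iv)] = recip_allele

    distal = positions > xover
    rec_broken = broken_co.copy()
    rec_intact = intact_b.copy()
    rec_broken[distal] = intact_b[distal]
    rec_intact[distal] = np.full(n, recip_allele, dtype=np.int8)[distal]

    # red = daughter homozygous W distal; the recombinant carrying the
    # donor-homolog distal arm co-segregates with the other intact donor sister
    if initiating == "Y":
        red = np.stack([intact_a, rec_broken])       # both W distal
        white = np.stack([rec_intact, broken_oth])   # both Y distal
    else:
        # donor = Y: the recombinant broken chromatid is Y distal (white),
        # while the recombinant donor sister carries the W distal arm (red)
        red = np.stack([broken_oth, rec_intact])
        white = np.stack([intact_a, rec_broken])
    return np.vstack([red, white])


def sector_genotypes(tracks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-sector genotype codes from the four chromatid tracks."""
    def _states(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        s = np.full(a.shape, int(Genotype.HET), dtype=np.int8)
        s[(a == 0) & (b == 0)] = int(Genotype.HOM_W)
        s[(a == 1) & (b == 1)] = int(Genotype.HOM_Y)
        return s

    return _states(tracks[0], tracks[1]), _states(tracks[2], tracks[3])


def _fill_observable(truth: TruthRecord, tracks: np.ndarray, marker_map: MarkerMap) -> None:
    """Project the event onto the marker grid and record the observable class."""
    from .model import SectorPair, GenotypeTrack

    red_s, white_s = sector_genotypes(tracks)
    zeros = np.zeros(len(red_s))
    fb = np.zeros(len(red_s), dtype=bool)
    pair = SectorPair(
        truth.event_id,
        GenotypeTrack("red", red_s, zeros, fb),
        GenotypeTrack("white", white_s, zeros.copy(), fb.copy()),
        marker_map,
    )
    _, events, _ = _tracts.analyze_pair(pair)
    if not events:
        truth.obs_class = TractClass.NONE.value
        truth.obs_signature = ""
        truth.obs_timing = "G2"
        truth.obs_donor = "AMBIGUOUS"
        return
    ev = events[0]
    if ev.tract is None:
        truth.obs_class = TractClass.NONE.value
        truth.obs_signature = ""
        truth.obs_timing = "G2"
        truth.obs_donor = "AMBIGUOUS"
    else:
        truth.obs_class = ev.tract.tract_class.value
        truth.obs_signature = ev.tract.signature
        truth.obs_timing = ev.tract.timing.value
        truth.obs_donor = ev.tract.donor.value


def simulate_complex_tract(
    config: SimulationConfig,
    rng: np.random.Generator,
    marker_map: MarkerMap,
    n_patches: int = 2,
    event_id: str = "cx0",
):
    """A conversion tract with patchy heteroduplex repair (interior patches).

    With 0 patches this degenerates to a simple tract.
    """
    if config.p_complex <= 0 and n_patches > 0:
        raise ValueError("p_complex must be > 0 to simulate complex tracts")
    category = "COMPLEX" if n_patches > 0 else "SIMPLE"
    return simulate_event(
        config, rng, marker_map, event_id=event_id,
        force_category=category, force_patches=n_patches,
    )


# ---------------------------------------------------------------------------
# rendering and cohorts


def render_ratios(
    states: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    sector: str,
) -> RatioTrack:
    """Hybridization ratios for one sector: level(state) + N(0, noise_sd), clipped at 0."""
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    het, up, down = config.ratio_levels
    n = len(states)
    w = np.full(n, het, dtype=float)
    y = np.full(n, het, dtype=float)
    hw = states == int(Genotype.HOM_W)
    hy = states == int(Genotype.HOM_Y)
    w[hw], y[hw] = up, down
    w[hy], y[hy] = down, up
    if config.noise_sd > 0:
        w = w + rng.normal(0.0, config.noise_sd, n)
        y = y + rng.normal(0.0, config.noise_sd, n)
    return RatioTrack(sector, np.clip(w, 0.0, None), np.clip(y, 0.0, None))


def events_from_class_counts(counts: dict[str, int]) -> list:
    """Minimal analyzed-event objects with a prescribed class composition.

    Used for bookkeeping checks on published class tallies when per-event
    coordinates are not available.  Keys are TractClass values; NONE events
    carry no tract.
    """
    from .model import ConversionTract, CrossoverEvent, Donor, Timing, TractSegment

    template = {
        TractClass.SIMPLE_31.value: (["W31"], Timing.G2),
        TractClass.SIMPLE_40.value: (["W40"], Timing.G1),
        TractClass.HYBRID_4031.value: (["W40", "W31"], Timing.G1),
        TractClass.HYBRID_3140.value: (["W31", "W40"], Timing.G1),
        TractClass.HYBRID_314031.value: (["W31", "W40", "W31"], Timing.G1),
        TractClass.COMPLEX.value: (["W31", "22", "W31"], Timing.G2),
    }
    events = []
    i = 0
    for cls_name, n in counts.items():
        for _ in range(int(n)):
            cid = f"fixture{i:04d}"
            i += 1
            if cls_name == TractClass.NONE.value:
                events.append(
                    CrossoverEvent(cid, (1000, 1500), (1000, 1500), 1250, None)
                )
                continue
            labels, timing = template[cls_name]
            start = 10_000 * i
            segs = []
            for j, lab in enumerate(labels):
                s = start + 2000 * j
                e = s + 1500
                segs.append(
                    TractSegment(lab, s, e, (s - 500, s), (e, e + 500), 4)
                )
            span = (segs[0].start_bp, segs[-1].end_bp)
            tract = ConversionTract(
                segments=segs, tract_class=TractClass(cls_name),
                signature="-".join(labels), donor=Donor.W, initiating=Donor.Y,
                timing=timing, length_min=span[1] - span[0],
                length_mid=span[1] - span[0] + 500,
                length_max=span[1] - span[0] + 1000,
                dsb_region=(span[0] - 500, span[1] + 500), span=span,
                marker_range=(0, 0),
            )
            events.append(
                CrossoverEvent(cid, segs[0].flank_left, segs[-1].flank_right,
                               (span[0] + span[1]) // 2, tract)
            )
    return events


@dataclass
class Cohort:
    marker_map: MarkerMap
    colonies: list[tuple[str, RatioTrack, RatioTrack]]
    truth: pd.DataFrame
    genotypes: list[tuple[np.ndarray, np.ndarray]]  # noise-free sector states


def generate_cohort(n_events: int, config: SimulationConfig) -> Cohort:
    """One sectored colony (ratio-track pair + truth record) per event.

    A single global seed drives a splittable per-event stream
    (numpy SeedSequence.spawn), so cohorts are reproducible and events are
    independent of cohort size ordering.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_events + 1)
    map_rng = np.random.default_rng(children[0])
    marker_map = simulate_marker_map(config, map_rng)
    colonies = []
    genotypes = []
    records = []
    for i in range(n_events):
        rng = np.random.default_rng(children[i + 1])
        cid = f"colony{i:04d}"
        truth, tracks = simulate_event(config, rng, marker_map, event_id=cid)
        red_s, white_s = sector_genotypes(tracks)
        red_rt = render_ratios(red_s, config, rng, "red")
        white_rt = render_ratios(white_s, config, rng, "white")
        colonies.append((cid, red_rt, white_rt))
        genotypes.append((red_s, white_s))
        records.append(asdict(truth))
    truth_df = pd.DataFrame.from_records(records)
    return Cohort(marker_map, colonies, truth_df, genotypes)
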