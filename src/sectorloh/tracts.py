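"""Four-chromatid profile analysis: crossover detection, tract
reconstruction, classification, donor and timing inference.

Combining the genotype tracks of the two sectors of a colony exposes the
four chromatids of the G2 cell in which the crossover occurred.  Proximal to
the exchange the profile is 2:2 heterozygous (HET22); distal it is 2:2 with
the two sectors homozygous for opposite homologs (RECIP22).  The bridge
between the two regimes is the gene-conversion tract: 3:1 segments mark one
converted chromatid (S/G2 lesion), 4:0 segments mark both sisters converted
(G1 lesion replicated before repair).

The donor homolog is the one over-represented inside the tract; the
initiating (broken) homolog is the other, because the lesion-bearing
chromosome acts as recipient during repair.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .model import (
    ChromatidProfile,
    ConversionTract,
    CrossoverEvent,
    Donor,
    Genotype,
    ProfileLabel,
    SectorPair,
    Timing,
    TractClass,
    TractSegment,
    profile_label_name,
)

# (red, white) genotype -> profile label
_COMBINE = {
    (Genotype.HET, Genotype.HET): ProfileLabel.HET22,
    (Genotype.HOM_W, Genotype.HOM_Y): ProfileLabel.RECIP22,
    (Genotype.HOM_Y, Genotype.HOM_W): ProfileLabel.RECIP22,
    (Genotype.HOM_W, Genotype.HET): ProfileLabel.W31,
    (Genotype.HET, Genotype.HOM_W): ProfileLabel.W31,
    (Genotype.HOM_Y, Genotype.HET): ProfileLabel.Y31,
    (Genotype.HET, Genotype.HOM_Y): ProfileLabel.Y31,
    (Genotype.HOM_W, Genotype.HOM_W): ProfileLabel.W40,
    (Genotype.HOM_Y, Genotype.HOM_Y): ProfileLabel.Y40,
}
_W_CONTRIB = {Genotype.HET: 1, Genotype.HOM_W: 2, Genotype.HOM_Y: 0}


def combine_sectors(pair: SectorPair) -> ChromatidProfile:
    """Derive per-marker four-chromatid allele counts from a sector pair.

    Markers UNCALLED or hemizygous-flagged in either sector are UNKNOWN and
    carry w_count = -1; elsewhere w_count + y_count = 4 by construction.
    """
    n = len(pair.marker_map)
    labels = np.full(n, int(ProfileLabel.UNKNOWN), dtype=np.int8)
    w_count = np.full(n, -1, dtype=np.int8)
    red = pair.red.states
    white = pair.white.states
    for (r, w), lab in _COMBINE.items():
        mask = (red == r) & (white == w)
        labels[mask] = int(lab)
        w_count[mask] = _W_CONTRIB[r] + _W_CONTRIB[w]
    return ChromatidProfile(w_count=w_count, labels=labels)


# ---------------------------------------------------------------------------
# run collapsing


def collapse_profile(labels: np.ndarray, absorb_singletons: bool = True):
    """Collapse a profile-label array into maximal runs.

    UNKNOWN markers are absorbed into the run of the nearest preceding
    labeled marker (leading UNKNOWNs attach forward).  With
    ``absorb_singletons`` a run supported by a single labeled marker whose
    two neighboring runs agree is merged into them: one marker (~500 bp
    resolution) cannot support a segment against two agreeing flanks.

    Returns a list of [label_code, start_idx, end_idx, n_labeled].
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        return []
    known = labels != int(ProfileLabel.UNKNOWN)
    idx = np.flatnonzero(known)
    if len(idx) == 0:
        return [[int(ProfileLabel.UNKNOWN), 0, n - 1, 0]]
    pos = np.clip(np.searchsorted(idx, np.arange(n), side="right") - 1, 0, None)
    eff = labels[idx[pos]]
    change = np.flatnonzero(np.diff(eff)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [n - 1]])
    runs = [
        [int(eff[s]), int(s), int(e), int(known[s : e + 1].sum())]
        for s, e in zip(starts, ends)
    ]
    if not absorb_singletons:
        return runs
    changed = True
    while changed and len(runs) >= 3:
        changed = False
        for i in range(1, len(runs) - 1):
            if runs[i][3] == 1 and runs[i - 1][0] == runs[i + 1][0]:
                merged = [
                    runs[i - 1][0],
                    runs[i - 1][1],
                    runs[i + 1][2],
                    runs[i - 1][3] + runs[i][3] + runs[i + 1][3],
                ]
                runs[i - 1 : i + 2] = [merged]
                changed = True
                break
    return runs


# ---------------------------------------------------------------------------
# classification


def classify_label_sequence(seq: Sequence[str]) -> tuple[TractClass, str]:
    """Map a collapsed segment-label sequence to a tract class.

    Simple and hybrid classes require a single donor and only 3:1/4:0
    segments in one of the canonical orders; anything else — interior 2:2
    patches, mixed donors, other shapes — is COMPLEX with a canonical
    signature string.
    """
    seq = list(seq)
    out: list[str] = []
    for lab in seq:  # defensive merge of adjacent duplicates
        if not out or out[-1] != lab:
            out.append(lab)
    signature = "-".join(out)
    if not out:
        return TractClass.NONE, ""
    donors = {lab[0] for lab in out if lab[0] in "WY"}
    kinds = [lab[1:] for lab in out]
    if len(donors) == 1 and all(k in ("31", "40") for k in kinds):
        if kinds == ["31"]:
            return TractClass.SIMPLE_31, signature
        if kinds == ["40"]:
            return TractClass.SIMPLE_40, signature
        if kinds == ["40", "31"]:
            return TractClass.HYBRID_4031, signature
        if kinds == ["31", "40"]:
            return TractClass.HYBRID_3140, signature
        if kinds == ["31", "40", "31"]:
            return TractClass.HYBRID_314031, signature
    return TractClass.COMPLEX, signature


def classify_tract(tract: ConversionTract) -> TractClass:
    cls, _ = classify_label_sequence([s.label for s in tract.segments])
    return cls


def infer_donor(tract: ConversionTract) -> tuple[Donor, Donor]:
    """Donor = homolog over-represented across tract segments by converted bp."""
    return _donor_from_segments(tract.segments)


def _donor_from_segments(segments: Sequence[TractSegment]) -> tuple[Donor, Donor]:
    w_bp = sum(s.end_bp - s.start_bp + 1 for s in segments if s.label.startswith("W"))
    y_bp = sum(s.end_bp - s.start_bp + 1 for s in segments if s.label.startswith("Y"))
    if w_bp > y_bp:
        return Donor.W, Donor.Y
    if y_bp > w_bp:
        return Donor.Y, Donor.W
    return Donor.AMBIGUOUS, Donor.AMBIGUOUS


def infer_timing(
    tract: ConversionTract,
    overrides: Optional[dict[str, Timing]] = None,
) -> Timing:
    """4:0-presence rule: any 4:0 segment means the lesion predates S phase.

    ``overrides`` maps class signatures to curated timings for complex
    shapes whose cell-cycle assignment needs expert judgment.
    """
    if overrides and tract.signature in overrides:
        return overrides[tract.signature]
    return _timing_from_labels([s.label for s in tract.segments])


def _timing_from_labels(labels: Sequence[str]) -> Timing:
    return Timing.G1 if any(l.endswith("40") for l in labels) else Timing.G2


def tract_lengths(
    span: tuple[int, int],
    outer_left: int,
    outer_right: int,
) -> tuple[int, int, int]:
    """(min, mid, max) tract lengths in bp.

    min spans the outermost converted markers; max spans the flanking
    unconverted markers; mid spans the midpoints of the two flanking
    transition intervals (the default reported length).
    """
    lo, hi = span
    length_min = hi - lo
    length_max = outer_right - outer_left
    length_mid = int(round((hi + outer_right) / 2 - (outer_left + lo) / 2))
    return length_min, length_mid, length_max


def event_point(event: CrossoverEvent, method: str = "tract_mid") -> int:
    """Represent an event as a single bp position (for point-analysis)."""
    if method == "tract_mid":
        if event.tract is not None and event.tract.segments:
            lo, hi = event.tract.span
            return (lo + hi) // 2
        lo = min(event.red_transition[0], event.white_transition[0])
        hi = max(event.red_transition[1], event.white_transition[1])
        return (lo + hi) // 2
    if method == "dsb_mid":
        if event.tract is not None and event.tract.segments:
            lo, hi = event.tract.dsb_region
            return (lo + hi) // 2
        return event_point(event, "tract_mid")
    raise ValueError(f"unknown event_point method: {method!r}")


# ---------------------------------------------------------------------------
# event detection


def analyze_profile(
    labels: np.ndarray,
    positions: np.ndarray,
    k: int = 10,
) -> tuple[list[dict], list[str]]:
    """Locate crossover events on a combined profile.

    A crossover is declared where the profile switches from a proximal HET22
    regime to a distal RECIP22 regime persisting through at least ``k``
    markers (or to the arm end / next event).  Runs strictly between the two
    regimes form the conversion tract.  A long distal homozygous regime that
    is not reciprocal is flagged and produces no event.

    Returns (raw event dicts, arm-level flags).
    """
    positions = np.asarray(positions)
    n = len(labels)
    runs = collapse_profile(labels)
    flags: list[str] = []

    def run_len(r):
        return r[2] - r[1] + 1

    events: list[dict] = []
    last_het: Optional[int] = None  # index into runs
    for i, r in enumerate(runs):
        lab, s, e, _ = r
        if lab == int(ProfileLabel.HET22) and (run_len(r) >= k or s == 0):
            last_het = i
        elif lab == int(ProfileLabel.RECIP22) and (run_len(r) >= k or e == n - 1):
            if run_len(r) < k:
                warnings.warn(
                    f"distal regime truncated at arm end ({run_len(r)} < {k} "
                    "markers); persistence threshold reduced",
                    stacklevel=2,
                )
            start_run = last_het + 1 if last_het is not None else 0
            tract_runs = [
                rr
                for rr in runs[start_run:i]
                if rr[0] != int(ProfileLabel.UNKNOWN)
            ]
            region_start = runs[start_run][1] if start_run < i else r[1]
            region_end = runs[i - 1][2] if start_run < i else r[1]
            unknown_frac = 0.0
            if region_end >= region_start:
                region = labels[region_start : region_end + 1]
                unknown_frac = float(
                    np.mean(region == int(ProfileLabel.UNKNOWN))
                )
            events.append(
                dict(
                    prox_run=last_het,
                    distal_run=i,
                    tract_runs=tract_runs,
                    distal_start=s,
                    prox_end=runs[last_het][2] if last_het is not None else None,
                    unknown_frac=unknown_frac,
                )
            )
            last_het = None
    if runs:
        lab, s, e, _ = runs[-1]
        if (
            lab in (int(ProfileLabel.W40), int(ProfileLabel.Y40))
            and e == n - 1
            and run_len(runs[-1]) >= k
        ):
            flags.append("NON_RECIPROCAL_DISTAL")
    return events, flags


def _sector_transition(
    states: np.ndarray,
    positions: np.ndarray,
    distal_start: int,
) -> tuple[int, int]:
    """Flanking-SNP pair bracketing a sector's terminal het->hom switch.

    Walks proximally from the distal regime through the maximal run of the
    sector's distal state; the transition interval runs from the nearest
    called marker with a different state to the start of that run.
    """
    called = np.flatnonzero(
        (states != Genotype.UNCALLED) & (states != Genotype.HEMIZYGOUS_LOSS)
    )
    if len(called) == 0:
        return int(positions[0]), int(positions[-1])
    j = np.searchsorted(called, distal_start, side="left")
    j = min(j, len(called) - 1)
    distal_state = states[called[j]]
    t = j
    while t > 0 and states[called[t - 1]] == distal_state:
        t -= 1
    right = int(positions[called[t]])
    left = int(positions[called[t - 1]]) if t > 0 else int(positions[0])
    return left, right


def _build_tract(
    tract_runs: list,
    positions: np.ndarray,
    ambiguous: bool,
    timing_overrides: Optional[dict[str, Timing]] = None,
) -> Optional[ConversionTract]:
    if not tract_runs:
        return None
    n = len(positions)
    segments: list[TractSegment] = []
    for lab, s, e, n_called in tract_runs:
        name = profile_label_name(lab)
        left_outer = int(positions[s - 1]) if s > 0 else int(positions[0])
        right_outer = int(positions[e + 1]) if e + 1 < n else int(positions[-1])
        segments.append(
            TractSegment(
                label=name,
                start_bp=int(positions[s]),
                end_bp=int(positions[e]),
                flank_left=(left_outer, int(positions[s])),
                flank_right=(int(positions[e]), right_outer),
                n_markers=int(e - s + 1),
            )
        )
    cls, signature = classify_label_sequence([seg.label for seg in segments])
    donor, initiating = _donor_from_segments(segments)
    timing = infer_timing_from_signature(signature, segments, timing_overrides)
    span = (segments[0].start_bp, segments[-1].end_bp)
    outer_left = segments[0].flank_left[0]
    outer_right = segments[-1].flank_right[1]
    lmin, lmid, lmax = tract_lengths(span, outer_left, outer_right)
    i0 = tract_runs[0][1]
    j1 = tract_runs[-1][2]
    return ConversionTract(
        segments=segments,
        tract_class=cls,
        signature=signature,
        donor=donor,
        initiating=initiating,
        timing=timing,
        length_min=lmin,
        length_mid=lmid,
        length_max=lmax,
        dsb_region=(outer_left, outer_right),
        span=span,
        marker_range=(int(i0), int(j1)),
        ambiguous=ambiguous,
    )


def infer_timing_from_signature(
    signature: str,
    segments: Sequence[TractSegment],
    overrides: Optional[dict[str, Timing]] = None,
) -> Timing:
    if overrides and signature in overrides:
        return overrides[signature]
    return _timing_from_labels([s.label for s in segments])


def analyze_pair(
    pair: SectorPair,
    k: int = 10,
    timing_overrides: Optional[dict[str, Timing]] = None,
    loss_regions: Optional[list[tuple[int, int]]] = None,
) -> tuple[ChromatidProfile, list[CrossoverEvent], list[str]]:
    """Full analysis of one sectored colony.

    Returns the combined profile, the detected crossover events (each with
    its reconstructed tract or None), and arm-level QC flags.  Events whose
    tract overlaps a hemizygous-loss region are flagged HEMIZYGOUS_OVERLAP
    and should be excluded from class statistics.
    """
    profile = combine_sectors(pair)
    positions = pair.marker_map.positions
    raw, flags = analyze_profile(profile.labels, positions, k=k)
    events: list[CrossoverEvent] = []
    for ev in raw:
        ambiguous = ev["unknown_frac"] > 0.5
        tract = _build_tract(ev["tract_runs"], positions, ambiguous, timing_overrides)
        red_tr = _sector_transition(pair.red.states, positions, ev["distal_start"])
        white_tr = _sector_transition(pair.white.states, positions, ev["distal_start"])
        event = CrossoverEvent(
            colony_id=pair.colony_id,
            red_transition=red_tr,
            white_transition=white_tr,
            point_bp=0,
            tract=tract,
        )
        event.point_bp = event_point(event, "tract_mid")
        if tract is not None and loss_regions:
            lo, hi = tract.dsb_region
            for a, b in loss_regions:
                if lo <= b and hi >= a:
                    event.qc_flags.append("HEMIZYGOUS_OVERLAP")
                    break
        events.append(event)
    for ev in events:
        ev.multiplicity = len(events)
    return profile, events, flags


def extract_tract(event: CrossoverEvent) -> Optional[ConversionTract]:
    """The conversion tract bridging the two sector transitions (or None)."""
    return event.tract
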