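"""Permutation tests for association of chromosome elements with
conversion tracts and their termini.

The null re-places every tract (or terminus window) uniformly at random on
the arm preserving its length — conditioning on the observed element map —
and the empirical p-value is (1 + #{null >= observed}) / (1 + n_perm) for
over-representation, mirrored for under-representation.  Strata (all / G1 /
G2 / initiating homolog) are analyzed separately and corrected for multiple
comparisons by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import ConversionTract, ElementTrack

STRATA = ("all", "G1", "G2", "W_initiated", "Y_initiated")


@dataclass
class EnrichmentConfig:
    n_permutations: int = 10_000
    seed: int = 0
    overlap_rule: str = "any_overlap"        # or "full_containment"
    counting: str = "per_tract_occurrences"  # or "distinct_elements"
    strata: tuple = STRATA
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.overlap_rule not in ("any_overlap", "full_containment"):
            raise ValueError(f"unknown overlap_rule: {self.overlap_rule!r}")
        if self.counting not in ("per_tract_occurrences", "distinct_elements"):
            raise ValueError(f"unknown counting: {self.counting!r}")


@dataclass
class EnrichmentResult:
    element_class: str
    stratum: str
    direction: str           # "over" / "under"
    observed: int
    null_mean: float
    p: float
    q: float = float("nan")
    n_tracts: int = 0
    flags: str = ""


# ---------------------------------------------------------------------------
# counting


def _occurrence_counts(starts: np.ndarray, ends: np.ndarray, elements: ElementTrack) -> np.ndarray:
    """#elements intersecting each [start, end] interval (vectorized).

    With elements sorted and non-overlapping, an element intersects iff
    el_start <= end and el_end >= start, so the count is
    #(el_start <= end) - #(el_end < start).
    """
    el_start = elements.intervals[:, 0]
    el_end = elements.intervals[:, 1]
    a = np.searchsorted(el_start, ends, side="right")
    b = np.searchsorted(el_end, starts, side="left")
    return a - b


def _containment_counts(starts: np.ndarray, ends: np.ndarray, elements: ElementTrack) -> np.ndarray:
    el = elements.intervals
    out = np.empty(len(starts), dtype=np.int64)
    for i, (s, e) in enumerate(zip(starts, ends)):
        out[i] = int(np.sum((el[:, 0] >= s) & (el[:, 1] <= e)))
    return out


def count_in_tracts(
    spans: Sequence[tuple[int, int]],
    elements: ElementTrack,
    config: Optional[EnrichmentConfig] = None,
) -> int:
    """Observed element count over a set of tract spans.

    ``per_tract_occurrences`` counts an element once per tract it
    intersects (an element spanning two tracts counts twice);
    ``distinct_elements`` counts each element at most once.
    """
    config = config or EnrichmentConfig()
    if len(spans) == 0 or len(elements) == 0:
        return 0
    starts = np.asarray([s for s, _ in spans], dtype=np.int64)
    ends = np.asarray([e for _, e in spans], dtype=np.int64)
    if config.counting == "distinct_elements":
        hit = np.zeros(len(elements), dtype=bool)
        el = elements.intervals
        for s, e in zip(starts, ends):
            if config.overlap_rule == "any_overlap":
                hit |= (el[:, 0] <= e) & (el[:, 1] >= s)
            else:
                hit |= (el[:, 0] >= s) & (el[:, 1] <= e)
        return int(hit.sum())
    fn = _occurrence_counts if config.overlap_rule == "any_overlap" else _containment_counts
    return int(fn(starts, ends, elements).sum())


# ---------------------------------------------------------------------------
# permutation null


def permutation_null(
    spans: Sequence[tuple[int, int]],
    elements: ElementTrack,
    arm: tuple[int, int],
    config: Optional[EnrichmentConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, float, float]:
    """Null distribution of the element count under random tract placement.

    Each permutation re-places every span uniformly on the arm preserving
    its length (overlaps between placed spans are allowed).  Returns
    (null counts, p_over, p_under); with no spans or elements the observed
    count is 0 and both p-values are 1.
    """
    config = config or EnrichmentConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = arm
    lens = np.asarray([e - s for s, e in spans], dtype=np.int64)
    if np.any(lens > hi - lo):
        raise ValueError("tract longer than the arm")
    obs = count_in_tracts(spans, elements, config)
    n_perm = config.n_permutations
    if len(spans) == 0 or len(elements) == 0:
        return np.zeros(n_perm, dtype=np.int64), 1.0, 1.0

    max_start = hi - lens  # inclusive upper bound for each span start
    if (
        config.counting == "per_tract_occurrences"
        and config.overlap_rule == "any_overlap"
    ):
        starts = rng.integers(lo, max_start + 1, size=(n_perm, len(lens)))
        ends = starts + lens
        el_start = elements.intervals[:, 0]
        el_end = elements.intervals[:, 1]
        a = np.searchsorted(el_start, ends.ravel(), side="right")
        b = np.searchsorted(el_end, starts.ravel(), side="left")
        null = (a - b).reshape(n_perm, len(lens)).sum(axis=1)
    else:
        null = np.empty(n_perm, dtype=np.int64)
        for i in range(n_perm):
            starts = rng.integers(lo, max_start + 1, size=len(lens))
            perm = [(int(s), int(s + L)) for s, L in zip(starts, lens)]
            null[i] = count_in_tracts(perm, elements, config)
    p_over = (1 + int(np.sum(null >= obs))) / (1 + n_perm)
    p_under = (1 + int(np.sum(null <= obs))) / (1 + n_perm)
    return null, float(p_over), float(p_under)


def terminus_association(
    tracts: Sequence[ConversionTract],
    elements: ElementTrack,
    arm: tuple[int, int],
    config: Optional[EnrichmentConfig] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Association of elements with tract termini.

    The terminus windows are the two het<->hom transition intervals of each
    tract; the null re-places the windows uniformly preserving widths.
    """
    windows = [w for t in tracts for w in t.terminus_windows]
    return windows, permutation_null(windows, elements, arm, config, rng)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (empty in -> empty out)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# report


def _stratum_filter(tracts: Sequence[ConversionTract], stratum: str):
    if stratum == "all":
        return list(tracts)
    if stratum in ("G1", "G2"):
        return [t for t in tracts if t.timing.value == stratum]
    if stratum.endswith("_initiated"):
        hom = stratum[0]
        return [t for t in tracts if t.initiating.value == hom]
    raise ValueError(f"unknown stratum: {stratum!r}")


def enrichment_report(
    tracts: Sequence[ConversionTract],
    element_tracks: dict[str, ElementTrack],
    arm: tuple[int, int],
    config: Optional[EnrichmentConfig] = None,
    termini: bool = False,
) -> pd.DataFrame:
    """Within-tract (or terminus) enrichment over all element classes and strata.

    One row per (element class x stratum x direction) with the observed
    count, permutation-null mean, empirical p and BH-adjusted q.
    Deterministic given the config seed.
    """
    config = config or EnrichmentConfig()
    rows: list[EnrichmentResult] = []
    rng = np.random.default_rng(config.seed)
    for name in sorted(element_tracks):
        elements = element_tracks[name]
        for stratum in config.strata:
            sub = _stratum_filter(tracts, stratum)
            if termini:
                spans = [w for t in sub for w in t.terminus_windows]
            else:
                spans = [t.span for t in sub]
            flags = ""
            if len(sub) == 0:
                null = np.zeros(0)
                p_over = p_under = 1.0
                obs = 0
                flags = "EMPTY_STRATUM"
            else:
                sub_rng = np.random.default_rng(rng.integers(2**31))
                null, p_over, p_under = permutation_null(
                    spans, elements, arm, config, sub_rng
                )
                obs = count_in_tracts(spans, elements, config)
            null_mean = float(null.mean()) if len(null) else 0.0
            for direction, p in (("over", p_over), ("under", p_under)):
                rows.append(
                    EnrichmentResult(
                        element_class=name, stratum=stratum, direction=direction,
                        observed=obs, null_mean=null_mean, p=p,
                        n_tracts=len(sub), flags=flags,
                    )
                )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["q"] = fdr_adjust(df["p"].to_numpy())
    return df
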