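"""Readers and writers for every file the pipeline touches.

Conventions
-----------
* Internal coordinates are 1-based inclusive (SGD convention); BED input is
  0-based half-open and converted at this boundary.
* Tables are tab-separated with a header row; ``#`` introduces comments.
* Readers reject silently-corrupting inputs (duplicate coordinates,
  inverted intervals) instead of coercing them.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .model import (
    ConversionTract,
    CrossoverEvent,
    ElementTrack,
    MarkerMap,
    RatioTrack,
)


# ---------------------------------------------------------------------------
# probe tables -> MarkerMap


def read_probe_table(path: str | Path) -> MarkerMap:
    """Build a MarkerMap from an allele-specific probe table.

    Expected columns: probe_name, background (W303a | YJM789), start_coord,
    end_coord, optionally sequence.  Each SNP is interrogated by probes for
    both genetic backgrounds; probes with overlapping coordinate spans form
    one marker whose position is the midpoint of the group span (rounded
    down).  Accepts per-probe or per-group coordinate spans.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no markers")
    required = {"probe_name", "background", "start_coord", "end_coord"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    df = df.copy()
    if not df["start_coord"].is_monotonic_increasing:
        warnings.warn(f"{path}: probe rows not sorted by coordinate; sorting")
    df.sort_values(["start_coord", "end_coord"], kind="stable", inplace=True)

    # sweep-line grouping of overlapping probe spans
    groups: list[list[int]] = []
    cur_end = -1
    for row in df.itertuples():
        if groups and row.start_coord <= cur_end:
            groups[-1].append(row.Index)
            cur_end = max(cur_end, int(row.end_coord))
        else:
            groups.append([row.Index])
            cur_end = int(row.end_coord)

    ids, positions = [], []
    for g in groups:
        sub = df.loc[g]
        alleles = set(sub["background"].astype(str))
        lo = int(sub["start_coord"].min())
        hi = int(sub["end_coord"].max())
        mid = (lo + hi) // 2
        if not {"W303a", "YJM789"} <= alleles:
            warnings.warn(
                f"{path}: marker at {mid} lacks probes for both alleles; dropped"
            )
            continue
        ids.append(f"snp{mid}")
        positions.append(mid)
    if not positions:
        raise ValueError(f"{path}: no markers")
    positions = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(positions) == 0):
        raise ValueError(f"{path}: duplicate marker coordinates")
    return MarkerMap("chrIV", np.asarray(ids, dtype=object), positions)


# ---------------------------------------------------------------------------
# ratio tables


def read_ratio_table(
    path: str | Path,
    marker_map: MarkerMap,
    sector: str = "sample",
    strand_combine: str = "mean",
) -> RatioTrack:
    """Read per-marker allele-specific ratios aligned to a MarkerMap.

    Accepts either pre-averaged columns (marker_id, w_ratio, y_ratio) or
    per-strand columns (w_watson, w_crick, y_watson, y_crick), which are
    combined per ``strand_combine`` (mean | min | median).  Rows may be in
    any order; every map marker must be present exactly once.  NaN ratios
    are kept and become UNCALLED downstream; negative ratios are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if "marker_id" not in df.columns:
        raise ValueError(f"{path}: missing marker_id column")
    comb = {"mean": np.nanmean, "min": np.nanmin, "median": np.nanmedian}
    if strand_combine not in comb:
        raise ValueError(f"unknown strand_combine: {strand_combine!r}")
    f = comb[strand_combine]
    if {"w_ratio", "y_ratio"} <= set(df.columns):
        w = df["w_ratio"].to_numpy(float)
        y = df["y_ratio"].to_numpy(float)
    elif {"w_watson", "w_crick", "y_watson", "y_crick"} <= set(df.columns):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN strand pair
            w = f(df[["w_watson", "w_crick"]].to_numpy(float), axis=1)
            y = f(df[["y_watson", "y_crick"]].to_numpy(float), axis=1)
    else:
        raise ValueError(f"{path}: no recognizable ratio columns")
    if np.any(w[~np.isnan(w)] < 0) or np.any(y[~np.isnan(y)] < 0):
        raise ValueError(f"{path}: negative hybridization ratio")

    table_ids = df["marker_id"].astype(str).to_numpy()
    order = {mid: i for i, mid in enumerate(table_ids)}
    missing = [str(mid) for mid in marker_map.ids if str(mid) not in order]
    if missing:
        raise ValueError(
            f"{path}: markers in map absent from table: {', '.join(missing[:10])}"
            + (" ..." if len(missing) > 10 else "")
        )
    extra = set(table_ids) - {str(m) for m in marker_map.ids}
    if extra:
        raise ValueError(
            f"{path}: table ids not in marker map: {', '.join(sorted(extra)[:10])}"
        )
    idx = np.asarray([order[str(mid)] for mid in marker_map.ids])
    return RatioTrack(sector, w[idx], y[idx])


def write_ratio_table(track: RatioTrack, marker_map: MarkerMap, path: str | Path) -> None:
    df = pd.DataFrame(
        {"marker_id": marker_map.ids, "w_ratio": track.w, "y_ratio": track.y}
    )
    # %.17g guarantees bit-exact float round trips through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# elements (BED)


def read_elements(
    path: str | Path,
    arm: Optional[tuple[int, int]] = None,
) -> dict[str, ElementTrack]:
    """Read BED3+ element annotations into per-class interval tracks.

    BED's 0-based half-open intervals become 1-based inclusive.  The 4th
    column carries the element class (default "element").  Abutting
    intervals of one class are merged; intervals outside ``arm`` are clipped
    with a warning.
    """
    path = Path(path)
    by_class: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            start0, end0 = int(parts[1]), int(parts[2])
            if start0 >= end0:
                raise ValueError(f"{path}:{lineno}: start >= end")
            s, e = start0 + 1, end0
            name = parts[3] if len(parts) > 3 else "element"
            if arm is not None:
                lo, hi = arm
                if e < lo or s > hi:
                    warnings.warn(f"{path}:{lineno}: interval outside arm; dropped")
                    continue
                if s < lo or e > hi:
                    warnings.warn(f"{path}:{lineno}: interval clipped to arm")
                    s, e = max(s, lo), min(e, hi)
            by_class.setdefault(name, []).append((s, e))
    return {
        name: ElementTrack(name, np.asarray(iv, dtype=np.int64))
        for name, iv in by_class.items()
    }


# ---------------------------------------------------------------------------
# event tables


_EVENT_COLUMNS = [
    "colony_id", "event_index", "multiplicity", "tract_class", "signature",
    "timing", "donor", "initiating", "red_left", "red_right", "white_left",
    "white_right", "tract_start", "tract_end", "length_min", "length_mid",
    "length_max", "dsb_left", "dsb_right", "point_bp", "segments", "qc_flags",
]


def events_to_frame(events: Iterable[CrossoverEvent]) -> pd.DataFrame:
    """Flatten analyzed events to the event-table layout.

    Each transition is reported as the pair of flanking SNP coordinates on
    both sides; segment runs are serialized as
    ``label:start-end`` joined with ``;``.
    """
    rows = []
    for i, ev in enumerate(events):
        t: Optional[ConversionTract] = ev.tract
        if t is not None and t.segments:
            segs = ";".join(f"{s.label}:{s.start_bp}-{s.end_bp}" for s in t.segments)
            row = dict(
                tract_class=t.tract_class.value, signature=t.signature,
                timing=t.timing.value, donor=t.donor.value,
                initiating=t.initiating.value,
                tract_start=t.span[0], tract_end=t.span[1],
                length_min=t.length_min, length_mid=t.length_mid,
                length_max=t.length_max,
                dsb_left=t.dsb_region[0], dsb_right=t.dsb_region[1],
                segments=segs,
            )
        else:
            row = dict(
                tract_class="NONE", signature="", timing="", donor="",
                initiating="", tract_start=-1, tract_end=-1, length_min=-1,
                length_mid=-1, length_max=-1, dsb_left=-1, dsb_right=-1,
                segments="",
            )
        row.update(
            colony_id=ev.colony_id, event_index=i, multiplicity=ev.multiplicity,
            red_left=ev.red_transition[0], red_right=ev.red_transition[1],
            white_left=ev.white_transition[0], white_right=ev.white_transition[1],
            point_bp=ev.point_bp, qc_flags=";".join(ev.qc_flags),
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_event_table(events, path: str | Path) -> None:
    """Write analyzed events (or a pre-built frame) as a deterministic TSV."""
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    df.to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"signature": str, "segments": str, "qc_flags": str},
                     keep_default_na=False, na_values=[])
    for col in ("event_index", "multiplicity", "red_left", "red_right",
                "white_left", "white_right", "tract_start", "tract_end",
                "length_min", "length_mid", "length_max", "dsb_left",
                "dsb_right", "point_bp"):
        df[col] = df[col].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# cohorts and configs


def write_cohort(cohort, out_dir: str | Path) -> None:
    """Persist a simulated cohort (marker map, ratio tables, truth table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        pd.DataFrame(
            {"marker_id": cohort.marker_map.ids,
             "position": cohort.marker_map.positions}
        ).to_csv(out / "marker_map.tsv", sep="\t", index=False)
        cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        for cid, red, white in cohort.colonies:
            write_ratio_table(red, cohort.marker_map, out / f"{cid}_red.tsv")
            write_ratio_table(white, cohort.marker_map, out / f"{cid}_white.tsv")
    except OSError as err:
        raise OSError(f"failed writing cohort to {out}: {err}") from err


def read_marker_map(path: str | Path, chromosome: str = "chrIV") -> MarkerMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    return MarkerMap(chromosome, df["marker_id"].astype(str).to_numpy(object),
                     df["position"].to_numpy(np.int64))


def load_cohort(in_dir: str | Path):
    """Re-read a cohort written by :func:`write_cohort` (bit-exact)."""
    from .simulate import Cohort

    d = Path(in_dir)
    marker_map = read_marker_map(d / "marker_map.tsv")
    truth = pd.read_csv(d / "truth.tsv", sep="\t",
                        dtype={"obs_signature": str}, keep_default_na=False,
                        na_values=[])
    colonies = []
    for cid in truth["event_id"]:
        red = read_ratio_table(d / f"{cid}_red.tsv", marker_map, sector="red")
        white = read_ratio_table(d / f"{cid}_white.tsv", marker_map, sector="white")
        colonies.append((cid, red, white))
    return Cohort(marker_map, colonies, truth, genotypes=[])


def save_config(config, path: str | Path) -> None:
    """Serialize a dataclass config (SimulationConfig etc.) to YAML."""
    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(config), fh, sort_keys=True)


def load_simulation_config(path: str | Path):
    from .simulate import Hotspot, SimulationConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "hotspots" in raw:
        raw["hotspots"] = [Hotspot(**h) for h in raw["hotspots"]]
    for tup in ("ratio_levels", "patch_len"):
        if tup in raw and isinstance(raw[tup], list):
            raw[tup] = tuple(raw[tup])
    return SimulationConfig(**raw)
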