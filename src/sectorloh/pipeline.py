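"""End-to-end orchestration: simulate/load -> call -> reconstruct ->
classify -> statistics -> enrichment, with deterministic outputs.

Tables are the contract; a manifest records the config hash and seed so a
run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as sio
from . import stats as sstats
from . import enrichment as senrich
from .calling import CallerConfig, arm_dosage_qc, call_track
from .model import CrossoverEvent, SectorPair, TractClass
from .simulate import Cohort, SimulationConfig, generate_cohort
from .tracts import analyze_pair, event_point

log = logging.getLogger("sectorloh")


@dataclass
class PipelineConfig:
    mode: str = "simulate"                  # "simulate" | "ratio_tables"
    n_events: int = 139
    seed: int = 0
    out_dir: str = "sectorloh_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    enrichment: senrich.EnrichmentConfig = field(
        default_factory=senrich.EnrichmentConfig
    )
    cohort_dir: Optional[str] = None        # ratio_tables mode input
    elements_bed: Optional[str] = None
    sector_frequency: Optional[float] = None
    arm_fraction_of_genome: float = 0.10
    n_map_regions: int = 20
    detection_k: int = 10
    point_method: str = "tract_mid"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ratio_tables"):
            raise ValueError(f"unknown input mode: {self.mode!r}")
        if self.mode == "ratio_tables" and not self.cohort_dir:
            raise ValueError("ratio_tables mode requires cohort_dir")
        # one global seed drives every stochastic stage
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)
        self.enrichment = dataclasses.replace(self.enrichment, seed=self.seed)


def analyze_cohort(
    cohort: Cohort,
    caller: Optional[CallerConfig] = None,
    k: int = 10,
    point_method: str = "tract_mid",
) -> tuple[list[CrossoverEvent], list[dict]]:
    """Call and analyze every colony of a cohort.

    Returns the flat event list plus per-colony QC records (dosage status,
    arm flags, detected event count).
    """
    caller = caller or CallerConfig()
    events: list[CrossoverEvent] = []
    qc: list[dict] = []
    positions = cohort.marker_map.positions
    for cid, red_rt, white_rt in cohort.colonies:
        red = call_track(red_rt, caller)
        white = call_track(white_rt, caller)
        red.sector, white.sector = "red", "white"
        dq_red = arm_dosage_qc(red_rt, positions)
        dq_white = arm_dosage_qc(white_rt, positions)
        loss = dq_red.loss_regions + dq_white.loss_regions
        pair = SectorPair(cid, red, white, cohort.marker_map)
        _, evs, flags = analyze_pair(pair, k=k, loss_regions=loss or None)
        for ev in evs:
            ev.point_bp = event_point(ev, point_method)
        events.extend(evs)
        qc.append(
            dict(
                colony_id=cid,
                dosage_red=dq_red.status,
                dosage_white=dq_white.status,
                n_loss_regions=len(loss),
                n_events=len(evs),
                flags=";".join(flags),
            )
        )
    return events, qc


def recovery_report(cohort: Cohort, events: list[CrossoverEvent]) -> dict:
    """Truth-vs-inferred comparison for a simulated cohort.

    Accuracy is measured against the marker-resolution observable truth;
    COMPLEX truths count as recovered when the inferred class is COMPLEX
    (signatures can legitimately differ under noise).  The crossover point
    must fall within one marker interval of the simulated exchange.
    """
    by_colony: dict[str, list[CrossoverEvent]] = {}
    for ev in events:
        by_colony.setdefault(ev.colony_id, []).append(ev)
    positions = cohort.marker_map.positions
    n = n_class = n_donor = n_timing = n_point = n_detected = 0
    n_strict = n_strict_total = 0
    for rec in cohort.truth.itertuples():
        n += 1
        evs = by_colony.get(rec.event_id, [])
        if len(evs) != 1:
            continue
        n_detected += 1
        ev = evs[0]
        inferred = ev.tract_class.value
        truth_cls = rec.obs_class
        ok_class = (
            inferred == truth_cls
            if truth_cls != TractClass.COMPLEX.value
            else inferred == TractClass.COMPLEX.value
        )
        n_class += ok_class
        if truth_cls not in (TractClass.COMPLEX.value, TractClass.NONE.value):
            n_strict_total += 1
            if ev.tract is not None:
                n_strict += (
                    inferred == truth_cls
                    and ev.tract.donor.value == rec.obs_donor
                    and ev.tract.timing.value == rec.obs_timing
                )
        if ev.tract is not None and truth_cls != TractClass.NONE.value:
            n_donor += ev.tract.donor.value == rec.obs_donor
            n_timing += ev.tract.timing.value == rec.obs_timing
        # crossover point: the distal-most sector transition (the conversion
        # shifts the other sector's transition to the tract's proximal end)
        # must bracket the simulated exchange within one marker interval
        lo, hi = max(ev.red_transition, ev.white_transition,
                     key=lambda tr: tr[1])
        j = np.searchsorted(positions, rec.xover_bp)
        lo_ok = positions[max(j - 2, 0)]
        hi_ok = positions[min(j + 1, len(positions) - 1)]
        n_point += (hi >= lo_ok) and (lo <= hi_ok)
    n_conv = int((cohort.truth["obs_class"] != TractClass.NONE.value).sum())
    return dict(
        n_truth=n,
        n_detected_once=n_detected,
        class_accuracy=n_class / n if n else float("nan"),
        donor_accuracy=n_donor / n_conv if n_conv else float("nan"),
        timing_accuracy=n_timing / n_conv if n_conv else float("nan"),
        strict_simple_accuracy=(
            n_strict / n_strict_total if n_strict_total else float("nan")
        ),
        xover_point_within_one_interval=n_point / n if n else float("nan"),
    )


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)     # where results land does not change them
    payload.pop("log_level", None)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the output-bundle paths and summary."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    stage = "input"
    try:
        if config.mode == "simulate":
            cohort = generate_cohort(config.n_events, config.simulation)
        else:
            cohort = sio.load_cohort(config.cohort_dir)
        log.info("stage %s done (%.1fs)", stage, time.monotonic() - t0)

        stage = "analysis"
        events, qc = analyze_cohort(
            cohort, config.caller, k=config.detection_k,
            point_method=config.point_method,
        )
        sio.write_event_table(events, out / "events.tsv")
        pd.DataFrame(qc).to_csv(out / "colony_qc.tsv", sep="\t", index=False)

        stage = "statistics"
        summary = sstats.cohort_summary(events)
        points = [ev.point_bp for ev in events]
        arm = (int(cohort.marker_map.positions[0]), int(cohort.marker_map.positions[-1]))
        bins = sstats.default_bin_edges()
        if not (bins[0] <= arm[0] and arm[1] <= bins[-1]):
            bins = sstats.default_bin_edges(arm)
        bin_res = sstats.bin_gof_test(points, bins)
        total_us = None
        rates = {}
        if config.sector_frequency is not None:
            est = sstats.crossover_rate(config.sector_frequency)
            gen = sstats.genome_extrapolation(est, config.arm_fraction_of_genome)
            total_us = est.microsterns
            rates = dict(
                sector_frequency=est.sector_frequency,
                crossover_rate=est.crossover_rate,
                arm_microsterns=est.microsterns,
                genome_rate=gen.crossover_rate,
                genome_microsterns=gen.microsterns,
            )
        gmap = sstats.genetic_map(
            points, config.n_map_regions, total_us if total_us else float(len(points)),
            arm=arm,
        )
        edges = np.linspace(arm[0], arm[1], config.n_map_regions + 1)
        pd.DataFrame(
            {"region_start": edges[:-1].astype(int),
             "region_end": edges[1:].astype(int),
             "map_width": gmap}
        ).to_csv(out / "genetic_map.tsv", sep="\t", index=False)

        tracts = [ev.tract for ev in events if ev.tract is not None
                  and not ev.qc_flags]
        spans = [t.span for t in tracts]
        involvement = sstats.snp_involvement_profile(spans, cohort.marker_map.positions)
        pd.DataFrame(
            {"marker_id": cohort.marker_map.ids,
             "position": cohort.marker_map.positions,
             "n_tracts": involvement}
        ).to_csv(out / "involvement.tsv", sep="\t", index=False)

        lengths = dict()
        g1 = [t.length_mid for t in tracts if t.timing.value == "G1"]
        g2 = [t.length_mid for t in tracts if t.timing.value == "G2"]
        alln = [t.length_mid for t in tracts]
        for name, vals in (("all", alln), ("G1", g1), ("G2", g2)):
            if vals:
                ci = sstats.median_ci(vals)
                lengths[name] = dict(
                    n=ci.n, median=ci.median, ci_lower=ci.lower,
                    ci_upper=ci.upper, coverage=ci.coverage,
                )
        if g1 and g2:
            u, p = sstats.mann_whitney(g1, g2)
            lengths["mann_whitney_G1_vs_G2"] = dict(U=u, p=p)

        stage = "enrichment"
        enr_paths = {}
        if config.elements_bed:
            element_tracks = sio.read_elements(config.elements_bed, arm=arm)
            rep = senrich.enrichment_report(
                tracts, element_tracks, arm, config.enrichment
            )
            rep.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            rep_t = senrich.enrichment_report(
                tracts, element_tracks, arm, config.enrichment, termini=True
            )
            rep_t.to_csv(out / "enrichment_termini.tsv", sep="\t", index=False)
            enr_paths = dict(enrichment="enrichment.tsv",
                             termini="enrichment_termini.tsv")

        stage = "reporting"
        report = dict(
            n_events=summary.n_events,
            by_class=summary.by_class,
            by_timing=summary.by_timing,
            by_initiating=summary.by_initiating,
            n_with_conversion=summary.n_with_conversion,
            fraction_with_conversion=summary.fraction_with_conversion,
            n_simple=summary.n_simple,
            bin_test=dict(chi2=bin_res.chi2, df=bin_res.df, p=bin_res.p,
                          observed=bin_res.observed.tolist()),
            rates=rates,
            tract_lengths=lengths,
        )
        if config.mode == "simulate":
            report["recovery"] = recovery_report(cohort, events)
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest = dict(
            config_hash=_config_hash(config), seed=config.seed,
            mode=config.mode, n_colonies=len(cohort.colonies),
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({config.mode} mode): {err}"
        ) from err
    log.info("pipeline complete in %.1fs", time.monotonic() - t0)
    return dict(out_dir=str(out), summary=report, manifest=manifest, **enr_paths)
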