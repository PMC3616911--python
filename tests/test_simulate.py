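"""Synthetic-data generator: marker maps, events, ratios, cohorts."""

import dataclasses

import numpy as np
import pytest

from sectorloh.model import Genotype, TractClass
from sectorloh.simulate import (
    Hotspot,
    SimulationConfig,
    generate_cohort,
    render_ratios,
    sector_genotypes,
    simulate_complex_tract,
    simulate_event,
    simulate_marker_map,
)


class TestMarkerMap:
    def test_default_density(self):
        mm = simulate_marker_map(SimulationConfig(seed=1))
        assert len(mm) == 2300
        spacing = np.diff(mm.positions).mean()
        assert 440 <= spacing <= 490  # ~466 bp over the 1.07-Mb arm
        assert mm.positions[0] >= 449_000 and mm.positions[-1] <= 1_520_000
        assert np.all(np.diff(mm.positions) > 0)

    def test_two_markers_are_endpoints(self):
        cfg = SimulationConfig(n_markers=2, marker_jitter=0)
        mm = simulate_marker_map(cfg)
        assert list(mm.positions) == [449_000, 1_520_000]

    def test_zero_jitter_equally_spaced_grid(self):
        cfg = SimulationConfig(
            arm_start=449_000, arm_end=460_000, n_markers=12, marker_jitter=0
        )
        mm = simulate_marker_map(cfg)
        expected = [449_000 + 1000 * i for i in range(12)]  # closed-form grid
        assert list(mm.positions) == expected

    def test_too_many_markers_raises(self):
        cfg = SimulationConfig(arm_start=1000, arm_end=1005, n_markers=10)
        with pytest.raises(ValueError):
            simulate_marker_map(cfg)


@pytest.fixture(scope="module")
def mm():
    return simulate_marker_map(SimulationConfig(seed=2))


def _first_event(cfg, mm, predicate, category="SIMPLE", max_tries=200):
    for i in range(max_tries):
        rng = np.random.default_rng(10_000 + i)
        truth, tracks = simulate_event(cfg, rng, mm, force_category=category)
        if predicate(truth):
            return truth, tracks
    raise AssertionError("no event matching predicate")


class TestEvents:
    def test_g2_event_three_to_one(self, mm):
        """A G2 lesion on Y leaves one converted chromatid: 3 W : 1 Y."""
        cfg = SimulationConfig(seed=0)
        truth, tracks = _first_event(
            cfg, mm, lambda t: t.timing == "G2" and t.initiating == "Y"
        )
        pos = mm.positions
        inside = (pos >= truth.extent_co_start) & (pos <= truth.extent_co_end)
        if inside.any():
            w_counts = 4 - tracks[:, inside].sum(axis=0)
            assert np.all(w_counts == 3)

    def test_g1_equal_extents_pure_40(self, mm):
        cfg = SimulationConfig(seed=0, p_full_extent=1.0)
        truth, tracks = _first_event(cfg, mm, lambda t: t.timing == "G1")
        pos = mm.positions
        inside = (pos >= truth.span_start) & (pos <= truth.span_end)
        if inside.any():
            w_counts = 4 - tracks[:, inside].sum(axis=0)
            target = 4 if truth.donor == "W" else 0
            assert np.all(w_counts == target)
            assert truth.obs_class == TractClass.SIMPLE_40.value

    def test_zero_length_tract_is_pure_crossover(self, mm):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(1)
        truth, tracks = simulate_event(cfg, rng, mm, force_category="NONE")
        assert truth.obs_class == TractClass.NONE.value
        red_s, white_s = sector_genotypes(tracks)
        pos = mm.positions
        prox = pos < truth.xover_bp
        dist = pos > truth.xover_bp
        assert np.all(red_s[prox] == int(Genotype.HET))
        assert np.all(white_s[prox] == int(Genotype.HET))
        hom = {int(Genotype.HOM_W), int(Genotype.HOM_Y)}
        assert set(red_s[dist]) | set(white_s[dist]) == hom
        assert len(set(red_s[dist])) == 1 and len(set(white_s[dist])) == 1

    def test_reciprocity_distal_of_crossover(self, mm):
        cfg = SimulationConfig(seed=0)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth, tracks = simulate_event(cfg, rng, mm, event_id=f"e{seed}")
            red_s, white_s = sector_genotypes(tracks)
            dist = mm.positions > truth.xover_bp
            assert dist.any()
            r, w = set(red_s[dist]), set(white_s[dist])
            assert len(r) == 1 and len(w) == 1 and r != w

    def test_allele_conservation(self, mm):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(4)
        _, tracks = simulate_event(cfg, rng, mm)
        assert tracks.shape == (4, len(mm))
        assert set(np.unique(tracks)) <= {0, 1}

    def test_donor_overrepresented_in_tract(self, mm):
        cfg = SimulationConfig(seed=0)
        truth, tracks = _first_event(
            cfg, mm,
            lambda t: t.obs_class not in ("NONE",) and t.span_end > t.span_start,
        )
        pos = mm.positions
        inside = (pos >= truth.span_start) & (pos <= truth.span_end)
        w_mean = (4 - tracks[:, inside].sum(axis=0)).mean()
        assert (w_mean > 2) == (truth.donor == "W")


class TestComplexTracts:
    def test_patchy_repair_yields_complex(self, mm):
        cfg = SimulationConfig(seed=0, patch_len=(1500, 2000),
                               tract_median_G1=20_000, tract_median_G2=20_000,
                               sigma_log=0.2)
        rng = np.random.default_rng(42)
        truth, _ = simulate_complex_tract(cfg, rng, mm, n_patches=2)
        assert truth.obs_class == TractClass.COMPLEX.value
        assert "22" in truth.obs_signature or "31" in truth.obs_signature

    def test_zero_patches_degenerates_to_simple(self, mm):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(7)
        truth, _ = simulate_complex_tract(cfg, rng, mm, n_patches=0)
        assert truth.category == "SIMPLE"
        assert truth.n_patches == 0

    def test_fixed_seed_reproducible(self, mm):
        cfg = SimulationConfig(seed=0)
        t1, tr1 = simulate_complex_tract(cfg, np.random.default_rng(9), mm)
        t2, tr2 = simulate_complex_tract(cfg, np.random.default_rng(9), mm)
        assert t1 == t2
        assert np.array_equal(tr1, tr2)


class TestRatios:
    def test_noise_free_levels(self, mm):
        cfg = SimulationConfig(noise_sd=0.0)
        states = np.asarray(
            [int(Genotype.HET), int(Genotype.HOM_W), int(Genotype.HOM_Y)], np.int8
        )
        rt = render_ratios(states, cfg, np.random.default_rng(0), "red")
        assert (rt.w[0], rt.y[0]) == (1.0, 1.0)
        assert (rt.w[1], rt.y[1]) == (1.6, 0.3)
        assert (rt.w[2], rt.y[2]) == (0.3, 1.6)

    def test_noise_model_sd(self):
        cfg = SimulationConfig(noise_sd=0.1)
        states = np.full(10_000, int(Genotype.HET), np.int8)
        rt = render_ratios(states, cfg, np.random.default_rng(123), "red")
        assert 0.095 <= rt.w.std(ddof=1) <= 0.105

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-0.1)


class TestCohorts:
    def test_category_mix_matches_config(self):
        cfg = SimulationConfig(seed=31)
        cohort = generate_cohort(139, cfg)
        counts = cohort.truth["category"].value_counts()
        for cat, p in (("NONE", 18 / 139), ("COMPLEX", 39 / 139),
                       ("SIMPLE", 82 / 139)):
            exp = 139 * p
            sd = np.sqrt(139 * p * (1 - p))
            assert abs(counts.get(cat, 0) - exp) <= 4 * sd

    def test_p_g1_law_of_large_numbers(self):
        """G1 fraction converges to p_G1 (unrestricted hotspot config)."""
        cfg = SimulationConfig(seed=17, hotspots=[], uniform_weight=1.0)
        cohort = generate_cohort(2000, cfg)
        frac = (cohort.truth["timing"] == "G1").mean()
        tol = 3 * np.sqrt((2 / 3) * (1 / 3) / 2000)
        assert abs(frac - 2 / 3) <= tol

    def test_all_none_when_forced(self):
        cfg = SimulationConfig(seed=5, p_no_conversion=1.0)
        cohort = generate_cohort(10, cfg)
        assert set(cohort.truth["category"]) == {"NONE"}
        assert set(cohort.truth["obs_class"]) == {TractClass.NONE.value}

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=8)
        c1 = generate_cohort(3, cfg)
        c2 = generate_cohort(3, cfg)
        assert c1.truth.equals(c2.truth)
        for (i1, r1, w1), (i2, r2, w2) in zip(c1.colonies, c2.colonies):
            assert i1 == i2
            assert np.array_equal(r1.w, r2.w) and np.array_equal(w1.y, w2.y)

    def test_n_events_validated(self):
        with pytest.raises(ValueError):
            generate_cohort(0, SimulationConfig())

    def test_hotspots_concentrate_g1_w_events(self):
        """Events near restricted hotspots are G1- and W-initiated."""
        hs = [Hotspot(981_000, 0.9, homolog="W", timing="G1")]
        cfg = SimulationConfig(seed=3, uniform_weight=0.1, hotspots=hs,
                               p_no_conversion=0.0)
        cohort = generate_cohort(200, cfg)
        near = cohort.truth["dsb_bp"].between(971_000, 991_000)
        sub = cohort.truth[near]
        assert len(sub) > 50
        # background events can also land in the window, but the hotspot
        # class dominates it
        assert (sub["timing"] == "G1").mean() > 0.9
        assert (sub["initiating"] == "W").mean() > 0.9

    def test_zero_weights_raise(self):
        cfg = SimulationConfig(uniform_weight=0.0, hotspots=[])
        mm_ = simulate_marker_map(dataclasses.replace(cfg, marker_jitter=0))
        with pytest.raises(ValueError):
            simulate_event(cfg, np.random.default_rng(0), mm_)
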