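"""Profile combination, crossover detection, tract classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_pair, make_track

from sectorloh.model import (
    Donor,
    Genotype,
    ProfileLabel,
    Timing,
    TractClass,
)
from sectorloh.tracts import (
    analyze_pair,
    classify_label_sequence,
    combine_sectors,
    event_point,
    tract_lengths,
)


class TestCombine:
    @pytest.mark.parametrize(
        "red,white,w_count,label",
        [
            ("h", "h", 2, ProfileLabel.HET22),
            ("W", "h", 3, ProfileLabel.W31),
            ("W", "W", 4, ProfileLabel.W40),
            ("W", "Y", 2, ProfileLabel.RECIP22),
            ("Y", "h", 1, ProfileLabel.Y31),
            ("Y", "Y", 0, ProfileLabel.Y40),
            (".", "h", -1, ProfileLabel.UNKNOWN),
        ],
    )
    def test_label_table(self, red, white, w_count, label):
        prof = combine_sectors(make_pair(red, white))
        assert prof.w_count[0] == w_count
        assert ProfileLabel(int(prof.labels[0])) == label

    def test_allele_conservation(self):
        """Wherever both sectors are called, W-count + Y-count = 4."""
        rng = np.random.default_rng(0)
        red = rng.choice([0, 1, 2, 3], size=300)
        white = rng.choice([0, 1, 2, 3], size=300)
        prof = combine_sectors(make_pair(red, white))
        known = prof.w_count >= 0
        assert np.all(prof.w_count[known] <= 4)
        both_called = (red != 3) & (white != 3)
        assert np.array_equal(known, both_called)


def _classify_oracle(seq):
    """Independent mapping-table oracle for the classifier."""
    out = []
    for lab in seq:
        if not out or out[-1] != lab:
            out.append(lab)
    if any(lab in ("22", "R22") for lab in out):
        return TractClass.COMPLEX
    donors = {lab[0] for lab in out}
    if len(donors) != 1:
        return TractClass.COMPLEX
    kinds = tuple(lab[1:] for lab in out)
    table = {
        ("31",): TractClass.SIMPLE_31,
        ("40",): TractClass.SIMPLE_40,
        ("40", "31"): TractClass.HYBRID_4031,
        ("31", "40"): TractClass.HYBRID_3140,
        ("31", "40", "31"): TractClass.HYBRID_314031,
    }
    return table.get(kinds, TractClass.COMPLEX)


class TestClassifier:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            (["W31"], TractClass.SIMPLE_31),
            (["W40"], TractClass.SIMPLE_40),
            (["W40", "W31"], TractClass.HYBRID_4031),
            (["W31", "W40", "W31"], TractClass.HYBRID_314031),
            (["W31", "Y31"], TractClass.COMPLEX),
            (["W31", "22", "W31"], TractClass.COMPLEX),
        ],
    )
    def test_examples(self, seq, expected):
        cls, sig = classify_label_sequence(seq)
        assert cls == expected
        if expected is TractClass.COMPLEX:
            assert sig == "-".join(seq)

    def test_equivalence_with_enumeration_oracle(self):
        """All label sequences of length <= 4 match the mapping-table oracle."""
        alphabet = ["W31", "W40", "Y31", "Y40", "22"]
        for n in range(1, 5):
            for seq in itertools.product(alphabet, repeat=n):
                cls, _ = classify_label_sequence(seq)
                assert cls == _classify_oracle(seq), seq


class TestDetection:
    def test_fig2_style_single_crossover(self):
        """Red hom-W from ~762.5 kb, white hom-Y from ~772 kb: one 3:1 tract."""
        # 500-bp spacing from 750 kb; red transition at marker 25, white at 44
        n = 100
        positions = 750_000 + 500 * np.arange(n)
        red = "h" * 25 + "W" * 75
        white = "h" * 44 + "Y" * 56
        pair = make_pair(red, white, positions)
        _, events, flags = analyze_pair(pair)
        assert len(events) == 1 and not flags
        ev = events[0]
        t = ev.tract
        assert t.tract_class == TractClass.SIMPLE_31
        assert t.donor == Donor.W and t.initiating == Donor.Y
        assert t.timing == Timing.G2
        assert ev.red_transition == (int(positions[24]), int(positions[25]))
        assert ev.white_transition == (int(positions[43]), int(positions[44]))

    def test_all_het_no_events(self):
        _, events, flags = analyze_pair(make_pair("h" * 60, "h" * 60))
        assert events == [] and flags == []

    def test_double_crossover_multiplicity(self):
        red = "h" * 30 + "W" * 30 + "h" * 30 + "W" * 30
        white = "h" * 30 + "Y" * 30 + "h" * 30 + "Y" * 30
        _, events, _ = analyze_pair(make_pair(red, white))
        assert len(events) == 2
        assert all(ev.multiplicity == 2 for ev in events)

    def test_non_reciprocal_distal_flagged(self):
        red = "h" * 40 + "W" * 40
        white = "h" * 40 + "W" * 40
        _, events, flags = analyze_pair(make_pair(red, white))
        assert events == []
        assert "NON_RECIPROCAL_DISTAL" in flags

    def test_coincident_transitions_class_none(self):
        red = "h" * 40 + "W" * 40
        white = "h" * 40 + "Y" * 40
        _, events, _ = analyze_pair(make_pair(red, white))
        assert len(events) == 1
        assert events[0].tract is None
        assert events[0].tract_class == TractClass.NONE

    def test_hybrid_two_segments(self):
        red = "h" * 30 + "W" * 50
        white = "h" * 30 + "W" * 20 + "h" * 10 + "Y" * 20
        _, events, _ = analyze_pair(make_pair(red, white))
        (ev,) = events
        assert [s.label for s in ev.tract.segments] == ["W40", "W31"]
        assert ev.tract.tract_class == TractClass.HYBRID_4031
        assert ev.tract.timing == Timing.G1

    def test_noise_singleton_absorbed(self):
        """One flipped marker inside a regime does not corrupt the class."""
        red = "h" * 12 + "W" + "h" * 17 + "W" * 50
        white = "h" * 45 + "Y" * 35
        _, events, _ = analyze_pair(make_pair(red, white))
        (ev,) = events
        assert ev.tract.tract_class == TractClass.SIMPLE_31

    def test_uncalled_majority_marks_ambiguous(self):
        red = "h" * 30 + "W" * 50
        white = "h" * 33 + "." * 10 + "Y" * 37
        _, events, _ = analyze_pair(make_pair(red, white))
        (ev,) = events
        assert ev.tract is not None and ev.tract.ambiguous

    def test_mixed_donor_ambiguous(self):
        # equal-span W31 then Y31 runs inside one tract
        red = "h" * 30 + "W" * 10 + "h" * 10 + "W" * 30
        white = "h" * 40 + "Y" * 40
        _, events, _ = analyze_pair(make_pair(red, white))
        (ev,) = events
        assert ev.tract.tract_class == TractClass.COMPLEX
        assert ev.tract.signature == "W31-Y31"
        assert ev.tract.donor == Donor.AMBIGUOUS


class TestLengthsAndPoints:
    def test_fig2_derived_lengths(self):
        lmin, lmid, lmax = tract_lengths((762_600, 771_900), 762_400, 772_100)
        assert (lmin, lmid, lmax) == (9_300, 9_500, 9_700)

    def test_single_marker_tract(self):
        lmin, lmid, lmax = tract_lengths((5_000, 5_000), 4_500, 5_500)
        assert (lmin, lmid, lmax) == (0, 500, 1_000)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 10_000), min_size=4, max_size=4, unique=True))
    def test_ordering_invariant(self, coords):
        a, b, c, d = sorted(coords)
        lmin, lmid, lmax = tract_lengths((b, c), a, d)
        assert lmin <= lmid <= lmax

    def test_event_point_tract_mid(self):
        red = "h" * 30 + "W" * 50
        white = "h" * 50 + "Y" * 30
        positions = 760_000 + 250 * np.arange(80)
        _, events, _ = analyze_pair(make_pair(red, white, positions))
        (ev,) = events
        lo, hi = ev.tract.span
        assert event_point(ev, "tract_mid") == (lo + hi) // 2
        assert abs(event_point(ev, "dsb_mid") - event_point(ev, "tract_mid")) <= 500

    def test_event_point_none_class(self):
        red = "h" * 40 + "W" * 40
        white = "h" * 40 + "Y" * 40
        positions = 900_000 - 40 * 12 + 12 * np.arange(80)  # ~12 bp spacing toy
        _, events, _ = analyze_pair(make_pair(red, white, positions))
        (ev,) = events
        lo = min(ev.red_transition[0], ev.white_transition[0])
        hi = max(ev.red_transition[1], ev.white_transition[1])
        assert event_point(ev) == (lo + hi) // 2

    def test_unknown_point_method_raises(self):
        red = "h" * 40 + "W" * 40
        white = "h" * 40 + "Y" * 40
        _, events, _ = analyze_pair(make_pair(red, white))
        with pytest.raises(ValueError):
            event_point(events[0], "nope")


def test_reciprocity_of_emitted_crossovers():
    """Every emitted crossover has a reciprocal distal regime."""
    rng = np.random.default_rng(5)
    for _ in range(20):
        cut = rng.integers(20, 60)
        tract = rng.integers(0, 15)
        red = "h" * cut + "W" * (80 - cut)
        white = "h" * min(80, cut + tract) + "Y" * max(0, 80 - cut - tract)
        pair = make_pair(red, white)
        _, events, _ = analyze_pair(pair)
        for ev in events:
            # distal states of the two sectors are homozygous and opposite
            r = Genotype(int(pair.red.states[-1]))
            w = Genotype(int(pair.white.states[-1]))
            assert {r, w} == {Genotype.HOM_W, Genotype.HOM_Y}
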