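"""Tract calling, recurrent filtering, classification and geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lohma
from lohma import (
    GT,
    Extent,
    LohTract,
    Mechanism,
    PARENT_S,
    PARENT_Y,
    SizeClass,
)
from conftest import make_snp_map

H, S, Y, M = GT.HET, GT.S_HOM, GT.Y_HOM, GT.MISSING


def brute_force_tracts(states, positions, min_support):
    """Independent run-length oracle: scan observed states left to right."""
    runs = []
    current_state, members = None, []
    for i, st_ in enumerate(states):
        if st_ == M:
            continue
        if st_ != current_state:
            if current_state in (S, Y) and len(members) >= min_support:
                runs.append((current_state, positions[members[0]], positions[members[-1]], len(members)))
            current_state, members = st_, []
        members.append(i)
    if current_state in (S, Y) and len(members) >= min_support:
        runs.append((current_state, positions[members[0]], positions[members[-1]], len(members)))
    return runs


def as_tuples(tracts):
    code = {PARENT_S: S, PARENT_Y: Y}
    return [(code[t.parent], t.start, t.end, t.n_supporting_snps) for t in tracts]


class TestCallTracts:
    def test_minimal_three_snp_tract(self, tiny_map):
        states = np.array([H, Y, Y, Y, H, H, H, H, H, H], dtype=np.int8)
        tracts = lohma.call_tracts(states, tiny_map, "L1")
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.parent, t.start, t.end, t.n_supporting_snps) == (
            PARENT_Y, 15_000, 35_000, 3,
        )

    def test_all_het_gives_nothing(self, tiny_map):
        assert lohma.call_tracts(np.full(10, H, dtype=np.int8), tiny_map) == []

    def test_short_run_rejected_long_run_kept(self, tiny_map):
        states = np.array([S, S, Y, Y, Y, H, H, H, H, H], dtype=np.int8)
        tracts = lohma.call_tracts(states, tiny_map)
        assert len(tracts) == 1
        assert tracts[0].parent == PARENT_Y

    def test_missing_neither_breaks_nor_supports(self, tiny_map):
        states = np.array([S, M, S, S, H, H, H, H, H, H], dtype=np.int8)
        tracts = lohma.call_tracts(states, tiny_map)
        assert len(tracts) == 1
        t = tracts[0]
        # run spans the MISSING site but support counts only observed SNPs
        assert (t.start, t.end, t.n_supporting_snps) == (5_000, 35_000, 3)
        # with support below threshold because of MISSING, no tract
        states2 = np.array([S, M, S, H, H, H, H, H, H, H], dtype=np.int8)
        assert lohma.call_tracts(states2, tiny_map) == []

    def test_midpoint_extension_mode(self, tiny_map):
        states = np.array([H, Y, Y, Y, H, H, H, H, H, H], dtype=np.int8)
        (t,) = lohma.call_tracts(states, tiny_map, extend_to_midpoints=True)
        # flanking HETs at 5000 and 45000 -> midpoints 10001 and 40000
        assert (t.start, t.end) == (10_001, 40_000)
        assert (t.snp_start, t.snp_end) == (15_000, 35_000)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        states=st.lists(st.sampled_from([H, S, Y, M]), min_size=1, max_size=40),
        min_support=st.integers(1, 4),
    )
    def test_matches_brute_force_oracle(self, states, min_support):
        positions = [10 * (i + 1) for i in range(len(states))]
        snp_map = make_snp_map({"chrI": positions})
        got = as_tuples(
            lohma.call_tracts(np.array(states, dtype=np.int8), snp_map, min_support=min_support)
        )
        assert got == brute_force_tracts(states, positions, min_support)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(states=st.lists(st.sampled_from([H, S, Y, M]), min_size=1, max_size=60))
    def test_tract_count_monotone_in_min_support(self, states):
        snp_map = make_snp_map({"chrI": [10 * (i + 1) for i in range(len(states))]})
        arr = np.array(states, dtype=np.int8)
        counts = [len(lohma.call_tracts(arr, snp_map, min_support=k)) for k in (1, 3, 5, 10)]
        assert counts == sorted(counts, reverse=True)


class TestRecurrentFilter:
    def _tract(self, line, start=100, end=500):
        return LohTract(line, "chrI", start, end, 3, PARENT_S)

    def test_present_in_all_lines_removed(self):
        lines = [f"L{i}" for i in range(10)]
        tracts = [self._tract(l) for l in lines] + [self._tract("L0", 700, 900)]
        kept, removed = lohma.filter_recurrent_tracts(tracts, lines)
        assert removed == 10
        assert [(t.start, t.end) for t in kept] == [(700, 900)]

    def test_present_in_nine_of_ten_kept(self):
        lines = [f"L{i}" for i in range(10)]
        tracts = [self._tract(l) for l in lines[:9]]
        kept, removed = lohma.filter_recurrent_tracts(tracts, lines)
        assert removed == 0 and len(kept) == 9

    def test_single_line_environment_untouched(self):
        tracts = [self._tract("L0")]
        kept, removed = lohma.filter_recurrent_tracts(tracts, ["L0"])
        assert removed == 0 and kept == tracts

    def test_min_shared_mode(self):
        tracts = [self._tract("L0"), self._tract("L1"), self._tract("L2", 700, 900)]
        kept, removed = lohma.filter_recurrent_tracts(
            tracts, ["L0", "L1", "L2"], require_all_lines=False, min_shared_lines=2
        )
        assert removed == 2 and len(kept) == 1


class TestClassification:
    def test_extent_rules(self):
        info = lohma.ChromInfo({"chrI": 200_000}, {"chrI": 100_000})

        def tract(start, end):
            return LohTract("L", "chrI", start, end, 3, PARENT_S)

        # one SNP inside the 20 kb window, others outside -> TERMINAL
        assert lohma.classify_extent(tract(175_000, 195_000), info) == Extent.TERMINAL
        # far from both ends -> INTERSTITIAL
        assert lohma.classify_extent(tract(50_000, 60_000), info) == Extent.INTERSTITIAL
        # entirely inside the window -> TERMINAL
        assert lohma.classify_extent(tract(185_000, 199_000), info) == Extent.TERMINAL
        # left end window counts too
        assert lohma.classify_extent(tract(1_000, 30_000), info) == Extent.TERMINAL
        with pytest.raises(KeyError):
            lohma.classify_extent(tract(1, 10), lohma.ChromInfo({}, {}))

    @pytest.mark.parametrize(
        "size,expected",
        [
            (1, SizeClass.SHORT),
            (999, SizeClass.SHORT),
            (1_000, SizeClass.MEDIUM),
            (9_999, SizeClass.MEDIUM),
            (10_000, SizeClass.LONG),
            (100_000, SizeClass.SUPER_LONG),
            (5_000_000, SizeClass.SUPER_LONG),
        ],
    )
    def test_size_class_boundaries(self, size, expected):
        assert lohma.size_class(size) == expected

    def test_size_class_domain_error(self):
        with pytest.raises(ValueError):
            lohma.size_class(0)

    def test_mechanism_thresholds(self, tiny_map):
        tract = LohTract("L", "chrI", 15_000, 35_000, 3, PARENT_S)
        mean_depth = 100.0

        def mech(s_val, y_val):
            s = np.full(10, 50.0)
            y = np.full(10, 50.0)
            s[1:4] = s_val
            y[1:4] = y_val
            return lohma.classify_mechanism(tract, tiny_map, s, y, mean_depth)

        assert mech(50, 2) == Mechanism.DELETION  # (0.50, 0.02)
        assert mech(100, 0) == Mechanism.RECOMBINATION  # copy-neutral (1.0, 0.0)
        assert mech(30, 5) == Mechanism.RECOMBINATION  # fails the 0.4-0.6 arm
        assert mech(40, 10) == Mechanism.DELETION  # inclusive boundaries
        nan = np.full(10, np.nan)
        assert (
            lohma.classify_mechanism(tract, tiny_map, nan, nan, mean_depth)
            == Mechanism.UNCLASSIFIED
        )
        with pytest.raises(ValueError):
            lohma.classify_mechanism(tract, tiny_map, nan, nan, 0.0)

    def test_tract_distances(self):
        info = lohma.ChromInfo({"chrI": 10_000}, {"chrI": 150})
        spanning = LohTract("L", "chrI", 100, 200, 3, PARENT_S)
        assert lohma.tract_distances(spanning, info) == (0, 99)
        mid = LohTract("L", "chrI", 1_000, 2_000, 3, PARENT_S)
        cen_d, tel_d = lohma.tract_distances(mid, info)
        assert cen_d == 850 and tel_d == 999  # min(999, 8000)
        at_start = LohTract("L", "chrI", 1, 50, 3, PARENT_S)
        assert lohma.tract_distances(at_start, info)[1] == 0


class TestMapsAndSummary:
    def test_loh_map_single_and_overlap(self):
        lengths = {"chrI": 100}
        one = [LohTract("L", "chrI", 10, 12, 3, PARENT_S)]
        m = lohma.loh_map(one, lengths)["chrI"]
        assert m[9:12].tolist() == [1, 1, 1] and m.sum() == 3
        two = one + [LohTract("L", "chrI", 11, 20, 3, PARENT_Y)]
        m2 = lohma.loh_map(two, lengths)["chrI"]
        assert m2.max() == 2 and m2.sum() == sum(t.size for t in two)
        assert lohma.loh_map([], lengths)["chrI"].sum() == 0

    def test_snp_density_bins(self):
        snp_map = make_snp_map({"chrI": [1, 50, 100, 101, 250]})
        dens = lohma.snp_density(snp_map, {"chrI": 300}, bin_bp=100)["chrI"]
        assert dens.tolist() == [3, 1, 1]
        assert dens.sum() == snp_map.n_snps

    def test_line_summary_rate_and_coverage(self, tiny_map):
        tracts = [
            LohTract("L", "chrI", i * 100 + 1, i * 100 + 100, 3, PARENT_S)
            for i in range(23)
        ]
        states = np.full(10, H, dtype=np.int8)
        summary = lohma.line_summary(tracts, tiny_map, states, generations=1000)
        assert summary.loh_rate_per_generation == pytest.approx(0.023)
        one = [LohTract("L", "chrI", 1, 240_400, 3, PARENT_S)]
        s2 = lohma.line_summary(one, tiny_map, states, generations=1000)
        assert s2.pct_genome_covered == pytest.approx(1.0)

    def test_line_summary_empty_and_fixed_fraction(self, tiny_map):
        states = np.array([S, S, Y, H, H, H, H, H, H, M], dtype=np.int8)
        summary = lohma.line_summary([], tiny_map, states, generations=1000)
        assert summary.n_tracts == 0
        assert summary.pct_genome_covered == 0.0
        assert summary.loh_rate_per_generation == 0.0
        assert summary.pct_snps_fixed == pytest.approx(30.0)
        with pytest.raises(ValueError):
            lohma.line_summary([], tiny_map, states, generations=0)
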