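"""Occupancy track construction, normalization and metaprofiles."""

import numpy as np
import pytest
from conftest import make_read, random_reads

from archscape import occupancy
from archscape.core import ChromatinStateAnnotation, GenomicInterval, OccupancyTrack


def _track(values, bin_width=10, chrom="chr1"):
    return OccupancyTrack(data={chrom: np.asarray(values, dtype=float)},
                          bin_width=bin_width)


class TestReadsToTrack:
    def test_single_read_bin_overlaps(self):
        # read [100,250) -> 80-nt interval [135,215) spread over 9 bins
        t = occupancy.reads_to_track([make_read("chr1", 100, 250)],
                                     chrom_sizes={"chr1": 300})
        v = t.data["chr1"]
        np.testing.assert_array_equal(
            v[13:22], [5, 10, 10, 10, 10, 10, 10, 10, 5])
        assert v.sum() == 80

    def test_linearity_two_identical_reads(self):
        one = occupancy.reads_to_track([make_read("chr1", 100, 250)],
                                       chrom_sizes={"chr1": 300})
        two = occupancy.reads_to_track([make_read("chr1", 100, 250)] * 2,
                                       chrom_sizes={"chr1": 300})
        np.testing.assert_array_equal(two.data["chr1"], 2 * one.data["chr1"])

    def test_mass_is_80_per_read_exactly(self, rng):
        reads = random_reads(rng, 3000, genome=100_000)
        t = occupancy.reads_to_track(reads, chrom_sizes={"chr1": 100_000})
        assert t.total_mass() == 80 * len(reads)
        assert t.clipped_mass == 0

    def test_clipping_at_chromosome_start_reported(self):
        t = occupancy.reads_to_track([make_read("chr1", 0, 20)])
        # center 10, interval [-30, 50) loses 30 bp at the left edge
        assert t.clipped_mass == 30
        assert t.total_mass() == 50

    def test_bin_cv_matches_sampling_oracle_at_20x(self):
        # oracle: uniform reads, overlap-weighted bins. A random 80-nt
        # interval overlaps a fixed 10-nt bin from 90 start offsets with
        # total overlap 800 and sum of squares 71*100 + 2*(1+..+81) = 7670,
        # so var(bin) ~= n * 90/G * E[o^2], mean = 80n/n_bins.
        rng = np.random.default_rng(3)
        genome, n = 40_000, 10_000  # 20x coverage
        reads = []
        for _ in range(n):
            length = int(rng.integers(147, 221))
            s = int(rng.integers(0, genome - length))
            reads.append(make_read("chr1", s, s + length))
        t = occupancy.reads_to_track(reads, chrom_sizes={"chr1": genome})
        v = t.data["chr1"][20:-20]  # interior bins, away from edge clipping
        e_o2 = (71 * 100 + 2 * sum(i * i for i in range(1, 10))) / 90
        cv_oracle = np.sqrt(n * (90 / genome) * e_o2) / (80 * n / (genome / 10))
        cv = v.std() / v.mean()
        assert cv == pytest.approx(cv_oracle, rel=0.10)

    def test_count_mode_assigns_full_mass_to_midpoint_bin(self):
        t = occupancy.reads_to_track([make_read("chr1", 100, 250)],
                                     chrom_sizes={"chr1": 300}, mode="count")
        v = t.data["chr1"]
        assert v[17] == 80 and v.sum() == 80


class TestSmoothing:
    def test_constant_track_unchanged(self):
        t = occupancy.smooth_track(_track([3.0] * 20))
        np.testing.assert_allclose(t.data["chr1"], 3.0)

    def test_impulse_spreads_quarter_half_quarter(self):
        t = occupancy.smooth_track(_track([0, 0, 80, 0, 0]))
        np.testing.assert_allclose(t.data["chr1"], [0, 20, 40, 20, 0])

    def test_mass_preserved_on_random_tracks(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = _track(rng.uniform(0, 100, size=rng.integers(2, 200)))
            sm = occupancy.smooth_track(t)
            assert abs(sm.total_mass() - t.total_mass()) < 1e-9


class TestQuantileNormalize:
    def test_rank_mean_example(self):
        tracks = {"a": _track([1, 2, 3]), "b": _track([4, 5, 6])}
        out = occupancy.quantile_normalize(tracks)
        np.testing.assert_allclose(out["a"].data["chr1"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"].data["chr1"], [2.5, 3.5, 4.5])

    def test_identical_tracks_unchanged(self):
        tracks = {"a": _track([5, 1, 7]), "b": _track([5, 1, 7])}
        out = occupancy.quantile_normalize(tracks)
        np.testing.assert_allclose(out["a"].data["chr1"], [5, 1, 7])

    def test_sorted_vectors_identical_and_idempotent(self, rng):
        tracks = {
            name: _track(rng.uniform(0, 10, 500)) for name in ("a", "b", "c")
        }
        out = occupancy.quantile_normalize(tracks)
        ref = np.sort(out["a"].data["chr1"])
        for name in ("b", "c"):
            np.testing.assert_array_equal(np.sort(out[name].data["chr1"]), ref)
        again = occupancy.quantile_normalize(out)
        for name in out:
            np.testing.assert_allclose(again[name].data["chr1"],
                                       out[name].data["chr1"], atol=1e-12)

    def test_permutation_equivariant_across_samples(self, rng):
        a, b = rng.uniform(0, 10, 100), rng.uniform(0, 10, 100)
        out1 = occupancy.quantile_normalize({"a": _track(a), "b": _track(b)})
        out2 = occupancy.quantile_normalize({"b": _track(b), "a": _track(a)})
        np.testing.assert_array_equal(out1["a"].data["chr1"],
                                      out2["a"].data["chr1"])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            occupancy.quantile_normalize({"a": _track([1, 2]), "b": _track([1])})

    def test_ties_averaged(self):
        out = occupancy.quantile_normalize(
            {"a": _track([1, 1, 4]), "b": _track([2, 3, 10])})
        # sample a has a tie at rank 1-2; both get the mean reference value
        va = out["a"].data["chr1"]
        assert va[0] == va[1] == pytest.approx((1.5 + 2.0) / 2)


def _states(*specs):
    return [
        ChromatinStateAnnotation(
            interval=GenomicInterval(chrom, s, e), state=state)
        for chrom, s, e, state in specs
    ]


class TestStateDensity:
    def test_uniform_track_every_state_mean_one(self):
        t = _track([1.0] * 100)
        states = _states(("chr1", 0, 400, "CS1"), ("chr1", 500, 900, "CS8"))
        res = occupancy.state_density(t, states)
        assert res == {"CS1": 1.0, "CS8": 1.0}
        change = occupancy.state_density_change(t, t, states)
        assert all(v["delta_pct"] == 0 for v in change.values())

    def test_scaled_track_gives_linear_percent_change(self, rng):
        vals = rng.uniform(1, 5, 200)
        wt = _track(vals)
        mut = _track(0.85 * vals)
        states = _states(("chr1", 30, 700, "CS8"), ("chr1", 900, 1800, "CS9"))
        change = occupancy.state_density_change(wt, mut, states)
        for s in ("CS8", "CS9"):
            assert change[s]["delta_pct"] == pytest.approx(-15.0, abs=1e-9)

    def test_missing_state_coverage_is_nan(self):
        t = _track([1.0] * 10)
        res = occupancy.state_density(t, _states(("chr9", 0, 100, "CS2")))
        assert np.isnan(res["CS2"])

    def test_matches_per_bp_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 10, 300)
        t = _track(vals)
        states = []  # disjoint intervals: states partition annotated regions
        for i in range(40):
            s = i * 75 + int(rng.integers(0, 40))
            e = s + int(rng.integers(1, 35))
            states.append(ChromatinStateAnnotation(
                interval=GenomicInterval("chr1", s, e),
                state=f"CS{1 + i % 9}"))
        res = occupancy.state_density(t, states)
        # oracle: expand track to per-bp values and average per state
        bp = np.repeat(vals, 10)
        for cs in {a.state for a in states}:
            sel = np.zeros(3000, dtype=bool)
            for a in states:
                if a.state == cs:
                    sel[a.interval.start:a.interval.end] = True
            # overlap-weighted bin mean == plain mean over covered bp
            assert res[cs] == pytest.approx(bp[sel].mean(), abs=1e-9)


class TestMetaProfile:
    def test_constant_track_flat_profile(self):
        t = _track([2.0] * 400)
        genes = [GenomicInterval("chr1", 2000, 3000, strand="+", name="g1")]
        prof = occupancy.metaprofile(t, genes, upstream=500, downstream=1000)
        np.testing.assert_allclose(prof.profiles["all"], 2.0)
        assert prof.n_elements["all"] == 1
        assert prof.offsets[0] == -500 and prof.offsets[-1] == 990

    def test_minus_strand_profile_is_reversed(self):
        ramp = np.arange(400, dtype=float)
        t = _track(ramp)
        plus = [GenomicInterval("chr1", 2000, 3000, strand="+", name="gp")]
        minus = [GenomicInterval("chr1", 1000, 2000, strand="-", name="gm")]
        pp = occupancy.metaprofile(t, plus, upstream=500, downstream=500)
        pm = occupancy.metaprofile(t, minus, upstream=500, downstream=500)
        # on a ramp, the minus-strand (reversed) profile decreases
        assert np.all(np.diff(pp.profiles["all"]) > 0)
        assert np.all(np.diff(pm.profiles["all"]) < 0)

    def test_superposition_recovers_common_shape(self, rng):
        # track built as identical bumps at each element anchor
        n_bins = 2000
        shape = np.zeros(n_bins)
        anchors = [300, 700, 1100, 1500]
        bump = np.array([1, 3, 7, 3, 1], dtype=float)
        for a in anchors:
            shape[a - 2 : a + 3] += bump
        t = _track(shape)
        genes = [GenomicInterval("chr1", a * 10, a * 10 + 500, strand="+",
                                 name=f"g{a}") for a in anchors]
        prof = occupancy.metaprofile(t, genes, upstream=100, downstream=100)
        center = len(prof.offsets) // 2
        np.testing.assert_allclose(prof.profiles["all"][center - 2 : center + 3],
                                   bump)

    def test_elements_outside_track_dropped_with_warning(self):
        t = _track([1.0] * 50)
        genes = [GenomicInterval("chr1", 10, 100, strand="+", name="g1")]
        with pytest.warns(UserWarning):
            prof = occupancy.metaprofile(t, genes, upstream=500, downstream=500)
        assert prof.profiles == {}

    def test_groups_split_profiles(self):
        t = _track(np.concatenate([np.full(200, 1.0), np.full(200, 9.0)]))
        genes = [GenomicInterval("chr1", 900, 1100, strand="+", name="lo"),
                 GenomicInterval("chr1", 2900, 3100, strand="+", name="hi")]
        prof = occupancy.metaprofile(t, genes, upstream=200, downstream=200,
                                     groups={"lo": "Q1", "hi": "Q5"})
        assert prof.profiles["Q1"].mean() == pytest.approx(1.0)
        assert prof.profiles["Q5"].mean() == pytest.approx(9.0)

    def test_scaled_body_resamples_to_fixed_bins(self):
        t = _track(np.arange(400, dtype=float))
        genes = [GenomicInterval("chr1", 1000, 3000, strand="+", name="g")]
        prof = occupancy.metaprofile(t, genes, anchor="scaled-body",
                                     body_bins=100)
        assert prof.profiles["all"].size == 50 + 100 + 50
        body = prof.profiles["all"][50:150]
        assert np.all(np.diff(body) > 0)  # monotone ramp preserved


class TestPhasingScore:
    def test_pure_cosine_recovers_period(self):
        x = np.cos(2 * np.pi * np.arange(100) * 10 / 175.0)
        period, amp = occupancy.phasing_score(x, bin_width=10)
        assert abs(period - 175) <= 10  # within one bin
        assert amp > 0.5

    def test_flat_profile_has_no_period(self):
        period, amp = occupancy.phasing_score(np.full(100, 4.2), bin_width=10)
        assert period is None and amp == 0.0

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            occupancy.phasing_score(np.ones(10), bin_width=10)
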