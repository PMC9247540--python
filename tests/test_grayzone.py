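import math

import numpy as np
import pytest
from scipy import stats

from fluidresp.grayzone import (
    GrayZone,
    GrayZoneSettings,
    bootstrap_cutoff_zone,
    combined_zone,
    triadic_zone,
)
from fluidresp.roc import DegenerateLabelsError


class TestTriadicZone:
    def test_six_point_example(self):
        z = triadic_zone([10, 20, 30, 40, 50, 60],
                         [False, False, False, True, True, True])
        # rule-out and rule-in bounds meet between 30 and 40
        assert z.width == 0.0
        assert z.lower == z.upper == 35.0

    def test_perfect_separation_is_empty(self):
        z = triadic_zone([1, 2, 3, 10, 11, 12],
                         [False, False, False, True, True, True])
        assert z.width == 0.0

    def test_zero_floors_give_empty_zone(self):
        z = triadic_zone([1, 2, 3, 10, 11, 12],
                         [False, False, False, True, True, True],
                         sn_floor=0.0, sp_floor=0.0)
        assert z.width == 0.0

    def test_overlapping_groups_give_nonempty_zone(self):
        rng = np.random.default_rng(0)
        s = np.r_[rng.normal(1.0, 1, 50), rng.normal(0, 1, 50)]
        y = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        z = triadic_zone(s, y)
        assert z.width > 0
        assert z.lower <= z.upper

    def test_raising_floors_never_shrinks_zone(self):
        rng = np.random.default_rng(1)
        s = np.r_[rng.normal(1.2, 1, 60), rng.normal(0, 1, 60)]
        y = np.r_[np.ones(60), np.zeros(60)].astype(bool)
        floors = [0.5, 0.7, 0.8, 0.9, 0.95, 0.99]
        prev = None
        for f in floors:
            z = triadic_zone(s, y, sn_floor=f, sp_floor=f)
            if prev is not None:
                assert z.width >= prev.width - 1e-12
                if prev.width > 0:  # nesting holds between non-empty zones
                    assert z.lower <= prev.lower + 1e-12
                    assert z.upper >= prev.upper - 1e-12
            prev = z

    def test_degenerate_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            triadic_zone([1, 2, 3], [True, True, True])


class TestBootstrapZone:
    def _overlap_data(self, n_per=50, seed=0):
        rng = np.random.default_rng(seed)
        s = np.r_[rng.normal(1.5, 1, n_per), rng.normal(0, 1, n_per)]
        y = np.r_[np.ones(n_per), np.zeros(n_per)].astype(bool)
        return s, y

    def test_seeded_determinism(self):
        s, y = self._overlap_data()
        a = bootstrap_cutoff_zone(s, y, n_boot=200, seed=42)
        b = bootstrap_cutoff_zone(s, y, n_boot=200, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        assert a.fractions == b.fractions

    def test_separated_groups_zone_stays_in_gap(self):
        s = np.r_[np.arange(10, 20), np.arange(40, 50)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(bool)
        z = bootstrap_cutoff_zone(s, y, n_boot=300, seed=1)
        assert 19 <= z.lower <= z.upper <= 40

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (100, 1000, 10000):
            s, y = self._overlap_data(n_per=n // 2, seed=9)
            z = bootstrap_cutoff_zone(s, y, n_boot=300, seed=2)
            widths.append(z.width)
        assert widths[2] < widths[1] < widths[0]

    def test_covers_analytic_density_crossing(self):
        # equal-variance binormal groups cross at the midpoint of the
        # means; the bootstrap zone should cover it in >= 90% of runs
        mu = 1.6
        crossing = mu / 2
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            s = np.r_[rng.normal(mu, 1, 250), rng.normal(0, 1, 250)]
            y = np.r_[np.ones(250), np.zeros(250)].astype(bool)
            z = bootstrap_cutoff_zone(s, y, n_boot=1000,
                                      seed=int(rng.integers(2**31)))
            hits += z.lower <= crossing <= z.upper
        assert hits / n_rep >= 0.90

    def test_n_boot_floor(self):
        s, y = self._overlap_data()
        with pytest.raises(ValueError):
            bootstrap_cutoff_zone(s, y, n_boot=50)

    def test_stratified_keeps_group_sizes(self):
        s, y = self._overlap_data()
        z = bootstrap_cutoff_zone(s, y, n_boot=200, seed=3, stratified=True)
        assert z.redrawn_replicates == 0


class TestCombinedZone:
    def test_wider_zone_wins(self):
        rng = np.random.default_rng(4)
        s = np.r_[rng.normal(1.0, 1, 40), rng.normal(0, 1, 60)]
        y = np.r_[np.ones(40), np.zeros(60)].astype(bool)
        z = combined_zone(s, y, GrayZoneSettings(n_boot=300, seed=5))
        assert z.method == "combined"
        wider = max(z.bootstrap_zone, z.triadic_zone, key=lambda g: g.width)
        assert z.width == wider.width
        assert (z.lower, z.upper) == (wider.lower, wider.upper)

    def test_equal_widths_prefer_triadic(self):
        # perfectly separated data often collapses both zones to width 0
        s = np.r_[np.arange(10.0, 16.0), np.arange(40.0, 46.0)]
        y = np.r_[np.zeros(6), np.ones(6)].astype(bool)
        z = combined_zone(s, y, GrayZoneSettings(n_boot=200, seed=6))
        if z.bootstrap_zone.width == z.triadic_zone.width:
            assert (z.lower, z.upper) == (z.triadic_zone.lower,
                                          z.triadic_zone.upper)

    def test_inconclusive_fraction_is_count_over_n(self):
        # 32 patients with exactly 9 marker values inside the zone
        s = np.r_[np.full(9, 45.0), np.full(13, 10.0), np.full(10, 80.0)]
        y = s >= 40.0
        y[:4] = False  # overlap so the zone is non-trivial
        frac = GrayZone(lower=35.0, upper=60.0, method="triadic",
                        fractions=(13 / 32, 9 / 32, 10 / 32)).fractions
        assert frac[1] == pytest.approx(0.28125)

    def test_fractions_sum_to_one_and_are_rational(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            n = int(rng.integers(10, 60))
            s = rng.normal(size=n)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                y[0] = ~y[0]
            z = combined_zone(s, y, GrayZoneSettings(n_boot=150, seed=seed))
            assert sum(z.fractions) == pytest.approx(1.0, abs=1e-9)
            for f in z.fractions:
                assert (f * n) == pytest.approx(round(f * n), abs=1e-9)
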