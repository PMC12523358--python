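"""The virtual-pasture generator: movement, deposition, decay, detection."""

import numpy as np
import pandas as pd
import pytest

from dungproxy import (Footprint, SimConfig, decompose, deposit_dung,
                       observe_dung, run_virtual_study, simulate_day,
                       simulate_pasture)
from dungproxy._rng import substream
from dungproxy.synthetic import _empty_pats
from conftest import tiny_config


class TestSimulatePasture:
    def test_default_area_matches_study_pasture(self):
        pasture = simulate_pasture(SimConfig())
        assert pasture.area_ha == pytest.approx(113.64, abs=1e-6)

    def test_square_side_from_area(self):
        pasture = simulate_pasture(SimConfig(pasture_area_ha=100.0))
        xmin, ymin, xmax, ymax = pasture.boundary.bounds
        assert xmax - xmin == pytest.approx(1000.0)

    def test_riverbed_disabled_absent(self):
        assert simulate_pasture(SimConfig(riverbed_enabled=False)).riverbed is None
        assert simulate_pasture(SimConfig()).riverbed is not None

    def test_oversized_buffer_is_error(self):
        with pytest.raises(ValueError):
            simulate_pasture(SimConfig(pasture_area_ha=1.0, fence_buffer_m=60))


class TestSimulateDay:
    def test_snapshot_count_in_design_range(self):
        cfg = SimConfig(herd_size=5)
        pasture = simulate_pasture(cfg)
        for seed in range(5):
            snaps = simulate_day(cfg, pasture, 5, 1, substream(seed, "m"))
            assert 12 <= len(snaps) <= 14
            assert all(s.herd_size == 5 for s in snaps)

    def test_empty_herd_gives_empty_snapshots(self):
        cfg = SimConfig(herd_size=0)
        pasture = simulate_pasture(cfg)
        snaps = simulate_day(cfg, pasture, 5, 1, substream(0, "m"))
        assert all(s.herd_size == 0 for s in snaps)

    def test_nonpositive_decay_length_is_error(self):
        cfg = SimConfig(movement_decay_length_m=-5)
        pasture = simulate_pasture(cfg)
        with pytest.raises(ValueError):
            simulate_day(cfg, pasture, 5, 1, substream(0, "m"))

    def test_large_lambda_approaches_uniform(self):
        """With a huge decay length (and persistence/pull off) positions are
        uniform: the mean distance to the campsite matches a Monte-Carlo
        uniform-square oracle within 3 standard errors."""
        cfg = SimConfig(herd_size=400, movement_decay_length_m=1e9,
                        movement_persistence=0.0, campsite_pull=0.0,
                        pen_radius_m=0.0, snapshots_per_day_range=(5, 5))
        pasture = simulate_pasture(cfg)
        cx, cy = pasture.campsite.x, pasture.campsite.y
        snaps = simulate_day(cfg, pasture, 5, 1, substream(7, "m"))
        pos = np.vstack([s.positions for s in snaps])
        d = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)

        oracle_rng = np.random.default_rng(99)
        xmin, ymin, xmax, ymax = pasture.boundary.bounds
        u = oracle_rng.uniform([xmin, ymin], [xmax, ymax], (200_000, 2))
        du = np.hypot(u[:, 0] - cx, u[:, 1] - cy)
        se = np.sqrt(du.var() / len(d) + du.var() / len(du))
        assert abs(d.mean() - du.mean()) < 3 * se

    def test_gradient_concentrates_near_campsite(self):
        cfg = SimConfig(herd_size=300, snapshots_per_day_range=(4, 4))
        pasture = simulate_pasture(cfg)
        cx, cy = pasture.campsite.x, pasture.campsite.y
        snaps = simulate_day(cfg, pasture, 5, 1, substream(3, "m"))
        pos = np.vstack([s.positions for s in snaps])
        d = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy).mean()
        side = pasture.boundary.bounds[2]
        assert d < 0.35 * side  # far below the uniform mean distance


class TestDepositDung:
    def setup_method(self):
        self.cfg = SimConfig(herd_size=50, deposition_rate=1.5)
        self.pasture = simulate_pasture(self.cfg)
        self.snaps = simulate_day(self.cfg, self.pasture, 5, 1,
                                  substream(1, "m"))

    def test_zero_rate_no_pats(self):
        cfg = self.cfg.model_copy(update={"deposition_rate": 0.0})
        pats = deposit_dung(self.snaps, cfg, self.pasture, substream(1, "d"))
        assert len(pats) == 0

    def test_poisson_mean_matches_yak_hours(self):
        """E[pats] = (yak-hours) * rate, observed within 3 sqrt(N r)."""
        n_yak_hours = sum(s.herd_size for s in self.snaps)
        expected = n_yak_hours * self.cfg.deposition_rate
        pats = deposit_dung(self.snaps, self.cfg, self.pasture,
                            substream(2, "d"))
        assert abs(len(pats) - expected) < 3 * np.sqrt(expected)

    def test_pats_inside_pasture(self):
        pats = deposit_dung(self.snaps, self.cfg, self.pasture,
                            substream(3, "d"))
        xmin, ymin, xmax, ymax = self.pasture.boundary.bounds
        assert pats.x_m.between(xmin, xmax).all()
        assert pats.y_m.between(ymin, ymax).all()

    def test_linear_in_rate_and_herd(self):
        """Deposition totals scale linearly with rate and herd size."""
        base = len(deposit_dung(self.snaps, self.cfg, self.pasture,
                                substream(4, "d")))
        cfg2 = self.cfg.model_copy(update={"deposition_rate": 3.0})
        doubled = len(deposit_dung(self.snaps, cfg2, self.pasture,
                                   substream(5, "d")))
        assert doubled / base == pytest.approx(2.0, abs=0.15)
        half_snaps = [s.__class__(s.month, s.day, s.hour, s.positions[:25])
                      for s in self.snaps]
        halved = len(deposit_dung(half_snaps, self.cfg, self.pasture,
                                  substream(6, "d")))
        assert halved / base == pytest.approx(0.5, abs=0.08)


def make_pats(n, t_dep=5.0, in_riverbed=0.0):
    return pd.DataFrame({
        "x_m": np.full(n, 100.0), "y_m": np.full(n, 100.0),
        "month": np.full(n, 5.0), "day": np.ones(n), "hour": np.full(n, 9.0),
        "t_dep": np.full(n, t_dep), "in_riverbed": np.full(n, in_riverbed),
        "checked_until": np.full(n, t_dep)})


class TestDecompose:
    def test_zero_decay_all_survive(self):
        cfg = SimConfig(decay_rate=0.0)
        pats = make_pats(500)
        assert len(decompose(pats, 10, cfg, substream(0, "k"))) == 500

    def test_half_life_compounds_to_quarter(self):
        """Monthly survival 0.5: ~25% alive after two monthly steps."""
        cfg = SimConfig(decay_rate=np.log(2.0))
        pats = make_pats(8000, t_dep=6.0)  # deposited exactly at June start
        s1 = decompose(pats, 6, cfg, substream(1, "k"))
        s2 = decompose(s1, 7, cfg, substream(2, "k"))
        frac = len(s2) / 8000
        se = np.sqrt(0.25 * 0.75 / 8000)
        assert abs(frac - 0.25) < 3 * se

    def test_zero_age_survives(self):
        cfg = SimConfig(decay_rate=5.0)
        pats = make_pats(100, t_dep=6.0)  # age 0 at the end of May
        assert len(decompose(pats, 5, cfg, substream(3, "k"))) == 100

    def test_riverbed_washout_faster(self):
        cfg = SimConfig(decay_rate=0.5, riverbed_decay_multiplier=4.0)
        dry = decompose(make_pats(4000), 5, cfg, substream(4, "k"))
        wet = decompose(make_pats(4000, in_riverbed=1.0), 5, cfg,
                        substream(5, "k"))
        assert len(wet) < len(dry)

    def test_survival_non_increasing_in_age_and_rate(self):
        cfg = SimConfig(decay_rate=0.4)
        old = decompose(make_pats(4000, t_dep=5.0), 8, cfg, substream(6, "k"))
        young = decompose(make_pats(4000, t_dep=8.0), 8, cfg, substream(7, "k"))
        assert len(old) <= len(young)
        fast = SimConfig(decay_rate=1.2)
        faster = decompose(make_pats(4000, t_dep=5.0), 8, fast, substream(6, "k"))
        assert len(faster) <= len(old)


class TestObserveDung:
    FP = Footprint((100.0, 100.0), 34.0, 26.0)

    def test_perfect_detection_counts_truth(self):
        cfg = SimConfig(detection_prob_by_height={20.0: 1.0},
                        false_positive_rate=0.0, gps_drift_max_m=0.0)
        s = observe_dung(make_pats(37), self.FP, 20.0, cfg, substream(0, "o"))
        assert s.observed_count == s.true_count == 37

    def test_zero_detection_sees_only_false_positives(self):
        cfg = SimConfig(detection_prob_by_height={20.0: 0.0},
                        false_positive_rate=0.0, gps_drift_max_m=0.0)
        s = observe_dung(make_pats(37), self.FP, 20.0, cfg, substream(1, "o"))
        assert s.observed_count == 0 and s.true_count == 37

    def test_unknown_height_is_error(self):
        cfg = SimConfig()
        with pytest.raises(ValueError, match="detection probability"):
            observe_dung(make_pats(5), self.FP, 10.0, cfg, substream(2, "o"))

    def test_detected_fraction_matches_configured_probability(self):
        """Mean detected fraction over >= 10,000 pats within 3 binomial SE
        of the configured 20 m detection probability."""
        p = 0.9316
        cfg = SimConfig(gps_drift_max_m=0.0, false_positive_rate=0.0)
        rng = substream(3, "o")
        total_true = total_det = 0
        for _ in range(5):
            s = observe_dung(make_pats(4000), self.FP, 20.0, cfg, rng)
            total_true += s.true_count
            total_det += s.detected_count
        assert total_true >= 10_000
        se = np.sqrt(p * (1 - p) / total_true)
        assert abs(total_det / total_true - p) < 3 * se

    def test_observed_never_exceeds_truth_without_false_positives(self):
        cfg = SimConfig(gps_drift_max_m=0.0, false_positive_rate=0.0)
        rng = substream(4, "o")
        for n in (0, 5, 200):
            s = observe_dung(make_pats(n), self.FP, 20.0, cfg, rng)
            assert s.observed_count <= s.true_count

    def test_empty_pats_table(self):
        cfg = SimConfig(gps_drift_max_m=0.0)
        s = observe_dung(_empty_pats(), self.FP, 2.0, cfg, substream(5, "o"))
        assert s.true_count == s.observed_count == 0


class TestRunVirtualStudy:
    def test_same_seed_bit_identical(self):
        with pytest.warns(UserWarning):
            a = run_virtual_study(tiny_config(seed=11))
        with pytest.warns(UserWarning):
            b = run_virtual_study(tiny_config(seed=11))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.pats, b.pats)
        for m in a.monthly_estimate:
            assert np.array_equal(a.monthly_estimate[m].values,
                                  b.monthly_estimate[m].values)

    def test_different_seed_differs(self):
        with pytest.warns(UserWarning):
            a = run_virtual_study(tiny_config(seed=11))
        with pytest.warns(UserWarning):
            b = run_virtual_study(tiny_config(seed=12))
        assert not a.counts.equals(b.counts)

    def test_six_monthly_datasets_may_to_october(self, tiny_study):
        assert sorted(tiny_study.monthly_estimate) == [5, 6, 7, 8, 9, 10]
        assert sorted(tiny_study.counts.month.unique()) == [5, 6, 7, 8, 9, 10]

    def test_truth_raster_carries_all_simulated_hours(self, tiny_study):
        cfg = tiny_study.config
        for m in cfg.months:
            expected = (cfg.herd_size * cfg.grazing_hours_per_day
                        * cfg.days_in_month[m])
            assert tiny_study.monthly_truth[m].total_yak_hours() == pytest.approx(
                expected, rel=1e-9)

    def test_no_decay_perfect_detection_proxy_correlation(self):
        """Dung density tracks true cumulative intensity (r > 0.95) when
        decay is off, detection perfect, and counts are large."""
        from dungproxy.kde import sample_intensity_at
        cfg = tiny_config(seed=5, herd_size=120, decay_rate=0.0,
                          riverbed_decay_multiplier=1.0,
                          detection_prob_by_height={2.0: 1.0, 20.0: 1.0},
                          gps_drift_max_m=0.0, deposition_rate=5.0)
        with pytest.warns(UserWarning):
            ds = run_virtual_study(cfg)
        cum = ds.cumulative_truth(5, 10)
        sub = ds.counts[ds.counts.month == 10]
        dens = sub.observed_count / sub.footprint_area_m2
        intens = [sample_intensity_at(cum, ds.footprint_for(w))
                  for w in sub.waypoint_id]
        assert sub.true_count.mean() >= 20
        assert np.corrcoef(dens, intens)[0, 1] > 0.95
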