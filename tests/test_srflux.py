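import math

import numpy as np
import pytest

from acanthoflux.simulate import TrapSimConfig, simulate_trap_series
from acanthoflux.srflux import (
    BackgroundEstimate,
    CSrRatio,
    TrapBottle,
    TrapSeries,
    analyze_series,
    carbonate_sr_bound,
    compute_flux,
    estimate_background,
    estimate_carbon,
    flag_significant,
    flux_results_to_frame,
    poc_contribution,
    read_trap_csv,
    truncate,
    write_trap_csv,
)


def series_of(concs, volume=500.0, duration=14.0, area=0.66) -> TrapSeries:
    bottles = [
        TrapBottle(trap_id="t", bottle_id=f"B{i:02d}", duration_days=duration,
                   volume_ml=volume, sr_conc=c)
        for i, c in enumerate(concs)
    ]
    return TrapSeries(trap_id="t", bottles=bottles, collection_area=area)


class TestBackground:
    def test_high_bottles_excluded(self):
        bg = estimate_background(series_of([8.0, 8.0, 8.0, 20.0]))
        assert (bg.mean, bg.sd, bg.n_bottles_used) == (8.0, 0.0, 3)

    def test_sample_sd(self):
        bg = estimate_background(series_of([7.0, 8.0, 9.5]))
        assert bg.mean == pytest.approx(7.5)
        assert bg.sd == pytest.approx(math.sqrt(0.5), rel=1e-12)  # ≈0.7071
        assert bg.n_bottles_used == 2

    def test_all_bottles_above_cutoff_is_error(self):
        with pytest.raises(ValueError, match="cannot-estimate-background"):
            estimate_background(series_of([9.5, 10.0, 12.0]))

    def test_cutoff_is_strict(self):
        bg = estimate_background(series_of([8.0, 9.0, 8.0]))  # 9.0 excluded
        assert bg.n_bottles_used == 2


class TestSignificance:
    def test_clearly_elevated_bottle_flagged(self):
        series = series_of([8.0, 8.1, 7.9, 20.0])
        bg = estimate_background(series)
        flags = flag_significant(series, bg)
        assert flags["B03"] is True
        assert sum(flags.values()) == 1

    def test_exactly_at_threshold_not_significant(self):
        bg = BackgroundEstimate(mean=8.0, sd=0.1, n_bottles_used=5)
        series = series_of([8.0, 8.0, 8.2])  # 8.2 == mean + 2·sd
        flags = flag_significant(series, bg)
        assert flags["B02"] is False

    def test_simulated_spike_is_the_only_flag(self):
        # a 1000 µg spike into 500 mL elevates by 2.0 µg/mL ≫ 2×0.05
        cfg = TrapSimConfig(seed=8, background_sd=0.05, spikes=((4, 1000.0),))
        series, _ = simulate_trap_series(cfg)
        bg = estimate_background(series)
        flags = flag_significant(series, bg)
        assert flags == {b.bottle_id: (i == 4)
                         for i, b in enumerate(series.bottles)}


class TestComputeFlux:
    def test_hand_arithmetic(self):
        bottle = TrapBottle("t", "B00", duration_days=14.0, volume_ml=500.0,
                            sr_conc=10.0)
        bg = BackgroundEstimate(mean=8.0, sd=0.0, n_bottles_used=5)
        flux, sd = compute_flux(bottle, bg, area=0.66)
        assert flux == pytest.approx(1.0 / 9.24)  # ≈ 0.10823 mg m⁻² d⁻¹
        assert sd == pytest.approx(0.1 * 0.5 / 9.24)

    def test_concentration_equal_to_background_gives_zero(self):
        bottle = TrapBottle("t", "B00", 14.0, 500.0, sr_conc=8.0)
        bg = BackgroundEstimate(mean=8.0, sd=0.0, n_bottles_used=5)
        assert compute_flux(bottle, bg)[0] == 0.0

    def test_uncertainty_quadrature(self):
        bottle = TrapBottle("t", "B00", 14.0, 500.0, sr_conc=10.0)
        bg = BackgroundEstimate(mean=8.0, sd=0.05, n_bottles_used=5)
        _, sd = compute_flux(bottle, bg, area=0.66)
        assert sd == pytest.approx(math.hypot(0.1, 0.05) * 0.5 / 9.24)  # ≈0.00605

    def test_unit_coherence(self):
        bg = BackgroundEstimate(mean=8.0, sd=0.0, n_bottles_used=5)
        base = TrapBottle("t", "B", 14.0, 500.0, sr_conc=10.0)
        f0, _ = compute_flux(base, bg, area=0.66)
        double_vol = TrapBottle("t", "B", 14.0, 1000.0, sr_conc=10.0)
        assert compute_flux(double_vol, bg, area=0.66)[0] == pytest.approx(2 * f0)
        double_area = compute_flux(base, bg, area=1.32)[0]
        assert double_area == pytest.approx(f0 / 2)
        double_time = TrapBottle("t", "B", 28.0, 500.0, sr_conc=10.0)
        assert compute_flux(double_time, bg, area=0.66)[0] == pytest.approx(f0 / 2)


class TestCarbonConversion:
    def test_printed_range_endpoints(self):
        low, _ = estimate_carbon(0.13, 0.0)
        high, _ = estimate_carbon(0.23, 0.0)
        assert truncate(low, 3) == 0.015
        assert truncate(high, 3) == 0.027

    def test_zero_flux_zero_uncertainty(self):
        assert estimate_carbon(0.0, 0.0) == (0.0, 0.0)

    def test_relative_quadrature(self):
        c, sd = estimate_carbon(0.2, 0.02, CSrRatio(0.120, 0.022))
        assert c == pytest.approx(0.024)
        rel = math.hypot(0.02 / 0.2, 0.022 / 0.120)
        assert sd == pytest.approx(0.024 * rel)


class TestPocContribution:
    def test_basic(self):
        assert poc_contribution(3.1, 100.0) == pytest.approx(3.1)
        assert poc_contribution(0.0, 10.0) == 0.0
        assert poc_contribution(0.05, 2.5) == pytest.approx(2.0)

    def test_scale_invariance(self):
        assert poc_contribution(0.05, 2.5) == pytest.approx(
            poc_contribution(0.05 * 7, 2.5 * 7)
        )

    def test_nonpositive_total_is_error(self):
        with pytest.raises(ValueError):
            poc_contribution(1.0, 0.0)


class TestCarbonateBound:
    @pytest.mark.parametrize("ca,ratio,expected",
                             [(300.0, 1.0, 0.3), (0.0, 1.0, 0.0), (100.0, 2.0, 0.2)])
    def test_bound(self, ca, ratio, expected):
        assert carbonate_sr_bound(ca, ratio) == pytest.approx(expected)

    def test_negative_elevation_is_error(self):
        with pytest.raises(ValueError):
            carbonate_sr_bound(-1.0)


class TestAnalyzeSeries:
    def test_fluxes_only_for_significant_bottles(self):
        series, truth = simulate_trap_series(TrapSimConfig(seed=13))
        bg, results = analyze_series(series)
        spiked = set(truth[truth.injected_sr_ug > 0].bottle_id)
        for r in results:
            if r.bottle_id in spiked:
                assert r.significant and r.sr_flux is not None
            else:
                assert r.sr_flux is None

    def test_recovered_flux_close_to_truth(self):
        series, truth = simulate_trap_series(TrapSimConfig(seed=13))
        _, results = analyze_series(series)
        truth_map = dict(zip(truth.bottle_id, truth.truth_sr_flux))
        for r in results:
            if r.significant:
                assert abs(r.sr_flux - truth_map[r.bottle_id]) < 2 * r.sr_flux_sd

    def test_poc_column_populated_when_table_given(self):
        series, truth = simulate_trap_series(TrapSimConfig(seed=13))
        spiked = truth[truth.injected_sr_ug > 0].bottle_id.tolist()
        poc = {b: 2.5 for b in spiked}
        _, results = analyze_series(series, total_poc_flux=poc)
        got = {r.bottle_id: r.poc_contribution_pct for r in results if r.significant}
        for b in spiked:
            assert got[b] == pytest.approx(100 *
                next(r.c_flux for r in results if r.bottle_id == b) / 2.5)

    def test_decisions_reproducible(self):
        series, _ = simulate_trap_series(TrapSimConfig(seed=21))
        first = flux_results_to_frame(analyze_series(series)[1])
        second = flux_results_to_frame(analyze_series(series)[1])
        assert first.equals(second)


class TestTrapCSV:
    def test_round_trip(self, tmp_path):
        series, _ = simulate_trap_series(TrapSimConfig(seed=2))
        path = tmp_path / "trap.csv"
        write_trap_csv(series, path)
        back = read_trap_csv(path)
        assert len(back) == 1
        assert [b.sr_conc for b in back[0].bottles] == pytest.approx(
            [b.sr_conc for b in series.bottles]
        )

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("trap_id,bottle_id\nt,b\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_trap_csv(path)
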