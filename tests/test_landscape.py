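"""Tests for signal normalization, smoothing, fold changes and profiles."""

import numpy as np
import pandas as pd
import pytest

import oracles
from pericentro import (
    SignalTrack,
    SuppressionModel,
    accounting_percent,
    cen_window_fold,
    chrom_log2_profile,
    distance_to_cen_profile,
    hann_smooth,
    interval_fold_change,
    loess_fit,
    metaplot_median,
    pericen_fold_change,
    rpm_normalize,
    simulate_chip_coverage,
    simulate_spo11_reads,
)
from pericentro.errors import InvalidParameterError, UndefinedFoldError
from pericentro.landscape import recovery_distance


def track_of(arrays: dict, total=None) -> SignalTrack:
    return SignalTrack(values={c: np.asarray(v, dtype=float) for c, v in arrays.items()}, total_mapped=total)


class TestRpmNormalize:
    def test_basic_scaling(self):
        t = track_of({"chrI": [0.0] * 10}, total=2_000_000)
        t.values["chrI"][3] = 50.0
        out = rpm_normalize(t)
        assert out.values["chrI"][3] == pytest.approx(25.0)
        assert out.units == "RPM"

    def test_self_total_sums_to_million(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(5, size=1000).astype(float)
        t = track_of({"chrI": vals}, total=float(vals.sum()))
        assert rpm_normalize(t).total() == pytest.approx(1e6)

    def test_scale_invariance(self):
        vals = np.arange(100, dtype=float)
        a = rpm_normalize(track_of({"c": vals}, total=1000.0))
        b = rpm_normalize(track_of({"c": vals * 7}, total=7000.0))
        np.testing.assert_allclose(a.values["c"], b.values["c"])

    def test_idempotent(self):
        t = rpm_normalize(track_of({"c": np.ones(10)}, total=100.0))
        np.testing.assert_array_equal(rpm_normalize(t).values["c"], t.values["c"])

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidParameterError):
            rpm_normalize(track_of({"c": np.zeros(5)}))


class TestHannSmooth:
    def test_constant_track_preserved_everywhere(self):
        t = track_of({"c": np.full(500, 3.25)})
        out = hann_smooth(t, window=201)
        np.testing.assert_allclose(out.values["c"], 3.25, rtol=1e-12)

    def test_impulse_peak_is_exactly_one_hundredth(self):
        # the un-normalized Hann sum for M=201 is exactly 100
        vals = np.zeros(1001)
        vals[500] = 1.0
        out = hann_smooth(track_of({"c": vals}), window=201)
        assert out.values["c"][500] == pytest.approx(0.01, abs=1e-15)

    def test_interior_signal_conserved(self):
        vals = np.zeros(2000)
        vals[900:1100] = np.random.default_rng(1).random(200)
        out = hann_smooth(track_of({"c": vals}), window=201)
        assert out.values["c"].sum() == pytest.approx(vals.sum(), rel=1e-12)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.poisson(3, size=10_000).astype(float)
        out = hann_smooth(track_of({"c": vals}), window=201)
        ref = oracles.hann_direct(vals, 201)
        np.testing.assert_allclose(out.values["c"], ref, atol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            hann_smooth(track_of({"c": np.ones(10)}), window=200)


class TestLoess:
    def test_reproduces_global_quadratic(self):
        """A degree-2 local fit is exact on a global quadratic."""
        x = np.linspace(0, 10, 80)
        y = 2.0 - 0.5 * x + 0.25 * x**2
        fit = loess_fit(x, y, span=0.4, degree=2)
        np.testing.assert_allclose(fit, y, atol=1e-8)

    def test_flat_data_flat_fit(self):
        x = np.arange(50, dtype=float)
        fit = loess_fit(x, np.full(50, 7.0), span=0.3)
        np.testing.assert_allclose(fit, 7.0, atol=1e-10)

    def test_nan_observations_dropped(self):
        x = np.arange(20, dtype=float)
        y = x.copy()
        y[5] = np.nan
        fit = loess_fit(x, y, span=0.5, degree=1, x_eval=np.array([10.0]))
        assert fit[0] == pytest.approx(10.0, abs=1e-8)


def three_chrom_tracks():
    """Hand-built 3-chromosome fixture with known segment sums."""
    rng = np.random.default_rng(42)
    cens = {}
    wt_vals, mut_vals = {}, {}
    for i, c in enumerate(["chrA", "chrB", "chrC"]):
        n = 100_000
        wt_vals[c] = rng.random(n) + 0.5
        mut_vals[c] = rng.random(n) + 0.5
        cens[c] = 50_000
    wt = SignalTrack(values=wt_vals, units="RPM")
    mut = SignalTrack(values=mut_vals, units="RPM")
    return wt, mut, cens


class TestPericenFoldChange:
    def test_identity_track_folds_one(self):
        wt, _, cens = three_chrom_tracks()
        table = pericen_fold_change(wt, wt, cens)
        assert np.allclose(table.folds["fold"], 1.0)
        assert np.allclose(table.stats["median"], 1.0)

    def test_flat_doubling(self):
        cens = {"chrA": 50_000}
        wt = SignalTrack(values={"chrA": np.full(100_000, 10.0 / 1000)}, units="RPM")
        mut = SignalTrack(values={"chrA": np.full(100_000, 20.0 / 1000)}, units="RPM")
        table = pericen_fold_change(wt, mut, cens)
        assert len(table.folds) == 12
        assert np.allclose(table.folds["fold"], 2.0)

    def test_matches_direct_summation_oracle(self):
        wt, mut, cens = three_chrom_tracks()
        table = pericen_fold_change(wt, mut, cens, bin=3000, span=36_000)
        for row in table.folds.itertuples():
            start = cens[row.chrom] + row.rel_start
            w = oracles.segment_density_direct(wt.values[row.chrom], start, start + 3000)
            m = oracles.segment_density_direct(mut.values[row.chrom], start, start + 3000)
            assert row.fold == pytest.approx(m / w, rel=1e-12)

    def test_span_must_be_multiple_of_bin(self):
        wt, mut, cens = three_chrom_tracks()
        with pytest.raises(InvalidParameterError):
            pericen_fold_change(wt, mut, cens, bin=3000, span=35_000)

    def test_recovers_planted_suppression_ratio(self):
        """Simulated suppressed vs unsuppressed tracks: the centromere-
        adjacent segment fold exceeds the outermost, and approximates the
        planted intensity ratio."""
        from pericentro import make_toy_genome

        genome = make_toy_genome(seed=7)
        model = SuppressionModel(dsb_floor=0.1, dsb_tau=1500.0)
        n = 2_000_000
        wt = rpm_normalize(simulate_spo11_reads(genome, model, suppression_on=True, total_reads=n, seed=1))
        mut = rpm_normalize(simulate_spo11_reads(genome, model, suppression_on=False, total_reads=n, seed=2))
        cens = genome.centromere_table()
        table = pericen_fold_change(wt, mut, cens)
        med = table.stats.set_index("rel_start")["median"]
        inner = (med.loc[-3000] + med.loc[0]) / 2  # segments flanking the centromere
        outer = (med.loc[-18_000] + med.loc[15_000]) / 2
        assert inner > outer
        assert outer == pytest.approx(1.0, abs=0.2)


class TestCenWindowFold:
    def test_identity_and_doubling(self):
        wt, _, cens = three_chrom_tracks()
        ones = cen_window_fold(wt, wt, cens)
        assert np.allclose(ones, 1.0) and len(ones) == 3
        doubled = SignalTrack(values={c: v * 2 for c, v in wt.values.items()}, units="RPM")
        assert np.allclose(cen_window_fold(wt, doubled, cens), 2.0)


class TestChromLog2Profile:
    def test_identity_zero(self):
        wt, _, _ = three_chrom_tracks()
        prof = chrom_log2_profile(wt, wt)
        assert np.allclose(prof["log2_fold"], 0.0)

    def test_fourfold_is_two(self):
        wt = SignalTrack(values={"c": np.full(20_000, 5.0)}, units="RPM")
        mut = SignalTrack(values={"c": np.full(20_000, 20.0)}, units="RPM")
        prof = chrom_log2_profile(wt, mut)
        assert np.allclose(prof["log2_fold"], 2.0, atol=0.01)

    def test_zero_bins_report_zero(self):
        wt = SignalTrack(values={"c": np.zeros(10_000)}, units="RPM")
        prof = chrom_log2_profile(wt, wt)
        assert np.allclose(prof["log2_fold"], 0.0)


class TestIntervalFold:
    def test_identity_and_value(self):
        wt = SignalTrack(values={"c": np.full(1000, 1.0)}, units="RPM")
        mut = SignalTrack(values={"c": np.full(1000, 5.0)}, units="RPM")
        assert interval_fold_change(wt, wt, "c", 100, 200) == pytest.approx(1.0)
        assert interval_fold_change(wt, mut, "c", 100, 200) == pytest.approx(5.0)

    def test_zero_wildtype_rejected(self):
        wt = SignalTrack(values={"c": np.zeros(1000)}, units="RPM")
        with pytest.raises(UndefinedFoldError):
            interval_fold_change(wt, wt, "c", 0, 100)

    def test_empty_interval_rejected(self):
        wt = SignalTrack(values={"c": np.ones(1000)}, units="RPM")
        with pytest.raises(InvalidParameterError):
            interval_fold_change(wt, wt, "c", 200, 200)


class TestAccounting:
    def test_headline_values(self):
        res = accounting_percent(5, 21)
        assert res.percent == pytest.approx(23.8095238, abs=1e-6)
        assert res.percent_rounded == 24

    def test_identity_and_quarter(self):
        assert accounting_percent(3.0, 3.0).percent == pytest.approx(100.0)
        assert accounting_percent(1, 4).percent == pytest.approx(25.0)

    def test_zero_co_fold_rejected(self):
        with pytest.raises(UndefinedFoldError):
            accounting_percent(1.0, 0.0)


class TestDistanceProfile:
    def test_flat_track_sits_at_genome_average(self):
        vals = {f"c{i}": np.full(200_000, 4.0) for i in range(3)}
        t = SignalTrack(values=vals, units="RPM")
        cens = {f"c{i}": 100_000 for i in range(3)}
        prof = distance_to_cen_profile(t, cens, ci_boot=20)
        assert prof.genome_average == pytest.approx(4.0)
        np.testing.assert_allclose(prof.mean, 4.0, rtol=1e-12)
        np.testing.assert_allclose(prof.loess, 4.0, rtol=1e-9)

    def test_short_arm_contributes_existing_bins(self):
        t = SignalTrack(values={"c": np.full(60_000, 1.0)}, units="RPM")
        prof = distance_to_cen_profile(t, {"c": 10_000}, ci_boot=10)
        # left arm is 10 kb, right arm 50 kb; bins beyond are NaN-padded
        assert prof.n_arms == 2
        assert np.isfinite(prof.mean[: 10_000 // 500]).all()

    def test_ci_brackets_fit(self):
        rng = np.random.default_rng(3)
        vals = {f"c{i}": rng.poisson(10, 200_000).astype(float) for i in range(4)}
        t = SignalTrack(values=vals, units="RPM")
        cens = {f"c{i}": 100_000 for i in range(4)}
        prof = distance_to_cen_profile(t, cens, ci_boot=50, seed=1)
        assert (prof.ci_low <= prof.ci_high).all()

    def test_suppressed_profile_rises_toward_plateau(self):
        """Planted exponential recovery: the loess profile rises from
        near the floor toward the plateau and crosses half-plateau within
        a factor-of-being of tau*ln2."""
        from pericentro import make_toy_genome

        genome = make_toy_genome(seed=7)
        model = SuppressionModel(dsb_floor=0.05, dsb_tau=1500.0)
        t = rpm_normalize(simulate_spo11_reads(genome, model, total_reads=4_000_000, seed=3))
        prof = distance_to_cen_profile(t, genome.centromere_table(), ci_boot=20, seed=0)
        # the raw first bin sits near the planted floor (the wide-span
        # loess is upward-biased inside the narrow suppressed zone)
        assert prof.mean[0] < 0.6 * prof.genome_average
        assert prof.loess[100:].mean() == pytest.approx(prof.genome_average, rel=0.2)
        d = recovery_distance(prof)
        assert np.isfinite(d) and 0 < d < 20_000


class TestMetaplotMedian:
    def test_single_centromere_is_own_profile(self):
        rng = np.random.default_rng(2)
        vals = rng.random(100_000)
        t = SignalTrack(values={"c": vals}, units="RPM")
        meta = metaplot_median(t, {"c": 50_000}, halfwidth=5000, bin=500)
        for row in meta.itertuples():
            lo = 50_000 + int(row.offset_start)
            assert row.median == pytest.approx(vals[lo : lo + 500].mean())

    def test_flat_track_flat_metaplot(self):
        t = SignalTrack(values={"a": np.full(100_000, 2.0), "b": np.full(100_000, 2.0)}, units="RPM")
        meta = metaplot_median(t, {"a": 40_000, "b": 60_000})
        np.testing.assert_allclose(meta["median"], 2.0)

    def test_planted_enrichment_ratio(self, small_genome):
        t = rpm_normalize(
            simulate_chip_coverage(small_genome, enrichment=4.0, halfwidth=20_000, total_reads=2_000_000, seed=4)
        )
        meta = metaplot_median(t, small_genome.centromere_table(), halfwidth=25_000, bin=500)
        center = meta.loc[meta["offset_center"].abs() < 1000, "median"].mean()
        flank = meta.loc[meta["offset_center"].abs() > 23_000, "median"].mean()
        assert center / flank == pytest.approx(4.0, rel=0.15)

    def test_empty_centromere_table_rejected(self):
        t = SignalTrack(values={"c": np.ones(1000)}, units="RPM")
        with pytest.raises(InvalidParameterError):
            metaplot_median(t, {})
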