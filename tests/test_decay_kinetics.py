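"""Delta-delta-Ct conversion, half-life fitting, censoring and correlation."""

import math

import numpy as np
import pytest
from scipy import stats

from rsmkit.decay_kinetics import (
    PAPER_TIMEPOINTS,
    AbundanceSeries,
    DecayTimeCourse,
    HalfLifeEstimate,
    Replicate,
    fit_halflife,
    fold_change,
    rank_correlation,
    relative_abundance,
    summarize_replicates,
)
from rsmkit.synthetic_data import DecaySpec, simulate_decay


def series_from_halflife(t_half, times=PAPER_TIMEPOINTS):
    rel = tuple(2.0 ** (-t / t_half) for t in times)
    return AbundanceSeries(tuple(times), rel)


def course(ct_target, ct_reference, times=None, efficiency=2.0):
    times = times or tuple(range(len(ct_target)))
    return DecayTimeCourse(
        "s", tuple(float(t) for t in times),
        (Replicate(tuple(ct_target), tuple(ct_reference)),), efficiency,
    )


class TestRelativeAbundance:
    def test_one_extra_cycle_halves_abundance(self):
        tc = course([20, 21, 22, 23], [10, 10, 10, 10])
        (series,) = relative_abundance(tc)
        assert series.rel_abundance == pytest.approx((1.0, 0.5, 0.25, 0.125))

    def test_normalized_to_one_at_time_zero(self):
        tc = course([18.3, 19.9, 22.1, 25.0], [9.7, 10.2, 10.1, 9.9])
        (series,) = relative_abundance(tc)
        assert series.rel_abundance[0] == 1.0

    def test_efficiency_below_two(self):
        # two extra cycles at efficiency 1.9
        tc = course([20, 20, 21, 22], [10, 10, 10, 10], efficiency=1.9)
        (series,) = relative_abundance(tc)
        expected = 1.9**-2
        assert series.rel_abundance[3] == pytest.approx(expected)
        assert series.rel_abundance[3] == pytest.approx(
            math.exp(-2 * math.log(1.9))  # log-domain cross-check
        )

    def test_nonfinite_point_dropped_with_warning(self, caplog):
        tc = course([20, 21, float("nan"), 23], [10, 10, 10, 10])
        with caplog.at_level("WARNING"):
            (series,) = relative_abundance(tc)
        assert len(series.times) == 3
        assert "non-finite" in caplog.text

    def test_missing_time_zero_rejected(self):
        tc = course([float("nan"), 21, 22, 23], [10, 10, 10, 10])
        with pytest.raises(ValueError):
            relative_abundance(tc)

    def test_reference_shift_invariance(self):
        # adding a constant to all reference Cts leaves the fit unchanged
        tgt = [20.0, 21.3, 22.9, 24.1, 26.0]
        ref = [10.0, 10.1, 9.9, 10.0, 10.2]
        t = (0.0, 5.0, 10.0, 15.0, 20.0)
        fit1 = fit_halflife(relative_abundance(course(tgt, ref, t))[0])
        ref_shift = [r + 3.7 for r in ref]
        tgt_shift = [x + 3.7 for x in tgt]
        fit2 = fit_halflife(relative_abundance(course(tgt_shift, ref_shift, t))[0])
        assert fit1.t_half == pytest.approx(fit2.t_half)


class TestFitHalflife:
    @pytest.mark.parametrize("t_half", [1.0, 10.0, 37.0, 90.0, 119.0])
    def test_exact_on_noise_free_exponential(self, t_half):
        est = fit_halflife(series_from_halflife(t_half), censor_at=120.0)
        assert not est.censored
        assert est.t_half == pytest.approx(t_half, rel=1e-9)

    def test_flat_series_censored(self):
        series = AbundanceSeries(PAPER_TIMEPOINTS, (1.0,) * len(PAPER_TIMEPOINTS))
        est = fit_halflife(series, censor_at=120.0)
        assert est.censored and est.censor_bound == 120.0

    def test_slow_decay_censored_at_default_last_time(self):
        est = fit_halflife(series_from_halflife(300.0))
        assert est.censored and est.censor_bound == 120.0

    def test_detection_floor_excludes_points(self):
        # fast decay: late points fall below floor but 3 early points remain
        est = fit_halflife(series_from_halflife(2.0))
        assert est.t_half == pytest.approx(2.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        series = AbundanceSeries((0.0, 1.0, 2.0, 5.0), (1.0, 0.5, 1e-5, 1e-6))
        with pytest.raises(ValueError):
            fit_halflife(series)

    def test_median_recovery_under_noise(self):
        # parameter recovery at the chase design's noise level
        estimates = []
        for i in range(1000):
            tc = simulate_decay(DecaySpec(true_t_half=37.0, noise_cv=0.1,
                                          n_replicates=1, seed=5000 + i))
            (series,) = relative_abundance(tc)
            estimates.append(fit_halflife(series).t_half)
        assert np.median(estimates) == pytest.approx(37.0, rel=0.05)

    def test_bias_and_rmse_monotone_in_noise(self):
        rmses = []
        for cv in (0.05, 0.1, 0.2):
            ests = []
            for i in range(400):
                tc = simulate_decay(DecaySpec(true_t_half=20.0, noise_cv=cv,
                                              n_replicates=1, seed=9000 + i))
                (series,) = relative_abundance(tc)
                ests.append(fit_halflife(series).t_half)
            ests = np.array(ests)
            assert abs(np.mean(ests) - 20.0) / 20.0 < 0.02
            rmses.append(float(np.sqrt(np.mean((ests - 20.0) ** 2))))
        assert rmses == sorted(rmses)

    def test_censoring_monotone_under_abundance_increase(self):
        # raising every abundance toward 1 never shortens the half-life
        base = series_from_halflife(30.0)
        est0 = fit_halflife(base, censor_at=120.0)
        for lam in (0.3, 0.6, 0.9):
            raised = AbundanceSeries(
                base.times,
                tuple(r + lam * (1 - r) for r in base.rel_abundance),
            )
            est = fit_halflife(raised, censor_at=120.0)
            reported = est.censor_bound if est.censored else est.t_half
            assert reported >= est0.t_half - 1e-9


class TestSummarizeReplicates:
    def test_mean_and_sample_sd(self):
        ests = [HalfLifeEstimate(v) for v in (36.0, 37.0, 38.0)]
        s = summarize_replicates(ests)
        assert (s.t_half, s.sd) == (37.0, pytest.approx(1.0))

    def test_mixed_censoring_flagged(self):
        s = summarize_replicates(
            [HalfLifeEstimate(40.0),
             HalfLifeEstimate(120.0, censored=True, censor_bound=120.0)]
        )
        assert s.censored and s.censor_bound == 120.0 and s.mixed

    def test_all_censored_takes_minimum_bound(self):
        s = summarize_replicates(
            [HalfLifeEstimate(90.0, censored=True, censor_bound=90.0),
             HalfLifeEstimate(120.0, censored=True, censor_bound=120.0)]
        )
        assert s.censored and s.censor_bound == 90.0 and not s.mixed

    def test_triplicate_simulation_recovers_truth(self):
        tc = simulate_decay(DecaySpec(true_t_half=53.0, noise_cv=0.02, seed=42))
        fits = [fit_halflife(s) for s in relative_abundance(tc)]
        s = summarize_replicates(fits)
        assert s.t_half == pytest.approx(53.0, abs=3.0)
        assert s.n_replicates == 3


class TestFoldChange:
    def test_eight_fold_stabilization(self):
        # stationary vs exponential phase half-lives in dilute medium
        fc = fold_change(HalfLifeEstimate(40.0), HalfLifeEstimate(5.0))
        assert fc.ratio == 8.0 and not fc.is_bound

    def test_identity_ratio(self):
        fc = fold_change(HalfLifeEstimate(17.0), HalfLifeEstimate(17.0))
        assert fc.ratio == 1.0

    def test_censored_numerator_gives_bound(self):
        fc = fold_change(
            HalfLifeEstimate(60.0, censored=True, censor_bound=60.0),
            HalfLifeEstimate(8.0),
        )
        assert fc.ratio == pytest.approx(7.5) and fc.is_bound
        assert str(fc) == ">=7.5"

    def test_two_censored_rejected(self):
        c = HalfLifeEstimate(60.0, censored=True, censor_bound=60.0)
        with pytest.raises(ValueError):
            fold_change(c, c)


def midrank_rho_oracle(x, keys):
    """Pearson on independently computed mid-ranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    return stats.pearsonr(midranks(list(x)), midranks(list(keys)))[0]


class TestRankCorrelation:
    def test_perfect_monotone(self):
        assert rank_correlation([1, 2, 3, 4], [5.0, 6.0, 7.0, 8.0]) == pytest.approx(1.0)

    def test_motif_counts_vs_rich_medium_halflives(self):
        x = [6, 6, 7, 10]
        y = [23.0, 16.0, 45.0, 53.0]
        rho = rank_correlation(x, y)
        assert rho == pytest.approx(midrank_rho_oracle(x, y))
        assert rho == pytest.approx(0.9487, abs=1e-3)

    def test_motif_counts_vs_censored_halflives(self):
        x = [6, 6, 7, 10]
        y = [
            HalfLifeEstimate(37.0),
            HalfLifeEstimate(40.0),
            HalfLifeEstimate(60.0, censored=True, censor_bound=60.0),
            HalfLifeEstimate(90.0, censored=True, censor_bound=90.0),
        ]
        rho = rank_correlation(x, y)
        # oracle: censored values rank above uncensored, ordered by bound
        assert rho == pytest.approx(midrank_rho_oracle(x, [1, 0, 2, 3]))
        assert rho == pytest.approx(0.9487, abs=1e-3)

    def test_constant_input_undefined(self):
        assert math.isnan(rank_correlation([3, 3, 3], [1.0, 2.0, 3.0]))


class TestSimulateDecay:
    def test_zero_noise_roundtrip_exact(self):
        tc = simulate_decay(DecaySpec(true_t_half=15.0, noise_cv=0.0, seed=1))
        for series in relative_abundance(tc):
            est = fit_halflife(series)
            assert est.t_half == pytest.approx(15.0, rel=1e-9)

    def test_fast_decay_never_censored(self):
        tc = simulate_decay(DecaySpec(true_t_half=5.0, noise_cv=0.1, seed=2))
        for series in relative_abundance(tc):
            assert not fit_halflife(series, censor_at=120.0).censored

    def test_very_slow_decay_always_censored(self):
        tc = simulate_decay(DecaySpec(true_t_half=300.0, noise_cv=0.1, seed=3))
        for series in relative_abundance(tc):
            est = fit_halflife(series, censor_at=120.0)
            assert est.censored and est.censor_bound == 120.0
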