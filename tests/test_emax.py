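"""Effect compartment and sigmoid-EMAX layer: lags, fits, LR test."""

import numpy as np
import pytest

from ventpkpd import (
    BiomarkerSeries,
    DoseEvent,
    PDParameters,
    compare_dynamics,
    concentration_fn,
    effect_site_concentration,
    emax_effect,
    fit_pd_biomarker,
    fit_pd_panel,
)
from ventpkpd.emax import _fraction


class TestEffectSite:
    def test_constant_input_half_life(self):
        ce = effect_site_concentration(lambda t: np.full_like(t, 5.0),
                                       h_half=0.9, times=[0.9])
        assert ce[0] == pytest.approx(2.5, rel=1e-4)

    def test_starts_at_zero(self):
        ce = effect_site_concentration(lambda t: np.full_like(t, 5.0),
                                       h_half=0.9, times=[0.0])
        assert ce[0] == 0.0

    def test_collapse_limit(self, median_pk):
        cp_fn = concentration_fn(median_pk, DoseEvent(200.0), 70.0)
        t = np.linspace(0.0, 8.0, 200)
        cp = cp_fn(t)
        ce = effect_site_concentration(cp_fn, h_half=1e-6, times=t)
        assert np.max(np.abs(ce - cp)) < 1e-3 * cp.max()

    def test_lag_delays_peak(self, median_pk):
        cp_fn = concentration_fn(median_pk, DoseEvent(200.0), 70.0)
        t = np.linspace(0.0, 8.0, 1600)
        cp = cp_fn(t)
        ce = effect_site_concentration(cp_fn, h_half=0.9, times=t)
        assert t[np.argmax(ce)] > t[np.argmax(cp)]
        assert ce.max() < cp.max()

    def test_time_shift_consistency(self, median_pk):
        # delaying the plasma curve delays the effect-site peak equally
        delay = 1.5
        cp_fn = concentration_fn(median_pk, DoseEvent(200.0), 70.0)
        cp_delayed = concentration_fn(median_pk, DoseEvent(200.0, time=delay),
                                      70.0)
        t = np.linspace(0.0, 12.0, 4801)
        ce0 = effect_site_concentration(cp_fn, 0.9, t)
        ce1 = effect_site_concentration(cp_delayed, 0.9, t)
        shift = t[np.argmax(ce1)] - t[np.argmax(ce0)]
        assert shift == pytest.approx(delay, abs=0.01)

    def test_invalid_h_half(self):
        with pytest.raises(ValueError):
            effect_site_concentration(lambda t: t, 0.0, [1.0])


class TestEmaxEffect:
    @pytest.mark.parametrize("ce,expected", [(0.0, 37.1), (0.08, 18.55),
                                             (0.24, 9.275)])
    def test_depressed_halving(self, ce, expected):
        pd = PDParameters(e0=37.1, c50=0.08, h_half=0.9, direction="depressed")
        assert emax_effect(pd, ce) == pytest.approx(expected)

    def test_elevated_doubling_at_c50(self):
        pd = PDParameters(e0=41.0, c50=0.81, h_half=1.3, direction="elevated")
        assert emax_effect(pd, 0.81) == pytest.approx(82.0)
        assert emax_effect(pd, 0.0) == pytest.approx(41.0)

    def test_depressed_bounded_and_monotone(self):
        pd = PDParameters(e0=10.0, c50=0.5, h_half=1.0, direction="depressed")
        ce = np.linspace(0.0, 50.0, 200)
        eff = emax_effect(pd, ce)
        assert np.all(eff > 0) and np.all(eff <= 10.0)
        assert np.all(np.diff(eff) < 0)

    def test_elevated_monotone(self):
        pd = PDParameters(e0=10.0, c50=0.5, h_half=1.0, direction="elevated")
        ce = np.linspace(0.0, 50.0, 200)
        eff = emax_effect(pd, ce)
        assert np.all(eff >= 10.0) and np.all(np.diff(eff) > 0)

    def test_rejects_negative_concentration(self):
        pd = PDParameters(e0=10.0, c50=0.5, h_half=1.0)
        with pytest.raises(ValueError):
            emax_effect(pd, -1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            PDParameters(e0=1.0, c50=0.0, h_half=1.0)
        with pytest.raises(ValueError):
            PDParameters(e0=1.0, c50=1.0, h_half=1.0, direction="sideways")


def _pd_series(cp_fns, subjects, e0s, c50, h_half, direction, sigma, rng,
               times=None):
    times = np.arange(0.0, 9.0) if times is None else times
    out = []
    for sid, e0 in zip(subjects, e0s):
        ce = effect_site_concentration(cp_fns[sid], h_half, times)
        pd = PDParameters(e0=e0, c50=c50, h_half=h_half, direction=direction)
        vals = emax_effect(pd, ce)
        if sigma > 0:
            vals = vals + sigma * rng.standard_normal(len(times))
        out.append(BiomarkerSeries(subject_id=sid, times=times, values=vals))
    return out


@pytest.fixture(scope="module")
def cp_fns(median_pk):
    fns = {}
    for i in range(12):
        dose = DoseEvent(100.0 if i % 2 else 200.0)
        fns[f"S{i:03d}"] = concentration_fn(median_pk, dose, 70.0)
    return fns


class TestFitPD:
    def test_zero_noise_single_subject_recovery(self, cp_fns):
        series = _pd_series(cp_fns, ["S000"], [37.1], 0.08, 0.9, "depressed",
                            0.0, None)
        fit = fit_pd_biomarker(series, cp_fns, "depressed", min_subjects=1)
        bf = fit.biomarkers["biomarker"]
        assert bf.c50 == pytest.approx(0.08, rel=1e-3)
        assert bf.h_half == pytest.approx(0.9, rel=1e-3)
        assert bf.e0_by_subject["S000"] == pytest.approx(37.1, rel=1e-3)

    def test_noisy_recovery_ve55_conditions(self, cp_fns):
        # published VE55 truth with its within-subject noise, 12 subjects:
        # median recovery over 5 replicates
        c50s, hs = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            subs = list(cp_fns)
            series = _pd_series(cp_fns, subs, [37.1] * len(subs), 0.08, 0.9,
                                "depressed", 3.46, rng)
            fit = fit_pd_biomarker(series, cp_fns, "depressed")
            c50s.append(fit.biomarkers["biomarker"].c50)
            hs.append(fit.biomarkers["biomarker"].h_half)
        assert abs(np.median(c50s) - 0.08) / 0.08 < 0.5
        assert abs(np.median(hs) - 0.9) < 0.3

    def test_constant_series_flagged(self, cp_fns):
        subs = list(cp_fns)[:6]
        times = np.arange(0.0, 9.0)
        series = [BiomarkerSeries(subject_id=s, times=times,
                                  values=np.full(9, 8.3)) for s in subs]
        with pytest.warns(UserWarning):
            fit = fit_pd_biomarker(series, cp_fns, "depressed")
        assert fit.flagged

    def test_preconditions(self, cp_fns):
        subs = list(cp_fns)[:3]
        times = np.arange(0.0, 9.0)
        series = [BiomarkerSeries(subject_id=s, times=times,
                                  values=np.full(9, 8.3)) for s in subs]
        with pytest.raises(ValueError):
            fit_pd_biomarker(series, cp_fns, "depressed")   # < 6 subjects

    def test_series_validation(self):
        with pytest.raises(ValueError):
            BiomarkerSeries("s", times=np.array([1.0, 2.0]),
                            values=np.array([1.0, 2.0]))    # missing t=0
        with pytest.raises(ValueError):
            BiomarkerSeries("s", times=np.array([0.0, 2.0, 2.0]),
                            values=np.array([1.0, 2.0, 3.0]))

    def test_hysteresis_collapse_matches_direct_emax(self, cp_fns):
        # tiny equilibration half-life: fitted curve equals the direct
        # EMAX of the plasma concentration
        t = np.arange(0.0, 9.0)
        cp = cp_fns["S000"](t)
        pd = PDParameters(e0=10.0, c50=0.1, h_half=1.0, direction="depressed")
        direct = emax_effect(pd, cp)
        ce = effect_site_concentration(cp_fns["S000"], 1e-5, t)
        via_ce = emax_effect(pd, ce)
        assert np.allclose(direct[1:], via_ce[1:], rtol=1e-3)


class TestCompareDynamics:
    def test_identical_copies_give_zero_statistic(self, cp_fns):
        subs = list(cp_fns)
        rng = np.random.default_rng(0)
        series = _pd_series(cp_fns, subs, [10.0] * 12, 0.4, 1.0, "depressed",
                            0.5, rng)
        panel = {"a": series, "b": series}
        dirs = {"a": "depressed", "b": "depressed"}
        shared = fit_pd_panel(panel, cp_fns, dirs, share_dynamics=True)
        separate = fit_pd_panel(panel, cp_fns, dirs, share_dynamics=False)
        test = compare_dynamics(shared, separate)
        assert test.statistic == pytest.approx(0.0, abs=1e-6)
        assert not test.significant

    def test_power_under_distinct_dynamics(self, cp_fns):
        # C50 0.81 versus 0.08 at n=12: the LR test should reject nearly
        # always; 20 replicates, at least 80% rejections
        subs = list(cp_fns)
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            panel = {
                "slow": _pd_series(cp_fns, subs, [8.3] * 12, 0.81, 1.3,
                                   "depressed", 0.44, rng),
                "fast": _pd_series(cp_fns, subs, [37.1] * 12, 0.08, 0.9,
                                   "depressed", 3.46, rng),
            }
            dirs = {"slow": "depressed", "fast": "depressed"}
            sigmas = {"slow": 0.44, "fast": 3.46}
            shared = fit_pd_panel(panel, cp_fns, dirs, sigmas=sigmas)
            separate = fit_pd_panel(panel, cp_fns, dirs, sigmas=sigmas,
                                    share_dynamics=False)
            if compare_dynamics(shared, separate).significant:
                hits += 1
        assert hits >= 0.8 * n_rep

    def test_non_nested_rejected(self, cp_fns):
        subs = list(cp_fns)
        rng = np.random.default_rng(2)
        series = _pd_series(cp_fns, subs, [10.0] * 12, 0.4, 1.0, "depressed",
                            0.5, rng)
        fit = fit_pd_panel({"a": series}, cp_fns, {"a": "depressed"})
        with pytest.raises(ValueError):
            compare_dynamics(fit, fit)
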