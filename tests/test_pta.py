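"""%T>MIC computation and probability-of-target-attainment simulation."""

import dataclasses

import numpy as np
import pytest

from meropk.popmodel import IIVSpec
from meropk.pta import (
    DosingRegimen,
    PTATarget,
    default_mic_grid,
    dose_multiplier,
    fraction_time_above_mic,
    mic_at_pta,
    pta_vs_albumin,
    pta_with_uncertainty,
    shift_pta_for_dose,
    simulate_pta,
)


class TestFractionTimeAboveMic:
    def test_always_above(self):
        assert fraction_time_above_mic(lambda t: np.full_like(t, 10.0), 2.0, 8.0) == 1.0

    def test_never_above(self):
        assert fraction_time_above_mic(lambda t: np.full_like(t, 1.0), 2.0, 8.0) == 0.0

    def test_monoexponential_closed_form(self):
        # C(t) = 10 exp(-0.1 t) crosses 5 at t = ln(2)/0.1; fraction = t/8
        frac = fraction_time_above_mic(lambda t: 10.0 * np.exp(-0.1 * t), 5.0, 8.0)
        assert frac == pytest.approx(np.log(2.0) / 0.1 / 8.0, abs=1e-6)

    def test_grid_fraction_agrees_with_root_finding(self, published_model):
        from meropk.pta import _fractions_above, _subject_profiles

        reg = DosingRegimen()
        etas = np.array([[0.3, -0.2, 0.1], [-0.4, 0.3, -0.2]])
        times = np.linspace(0.0, 8.0, 513)
        conc = _subject_profiles(published_model, reg, 24.6, etas, times)
        for i in range(2):
            grid_frac = _fractions_above(conc[i : i + 1], times, 2.0)[0]
            profile = lambda t, i=i: _subject_profiles(
                published_model, reg, 24.6, etas[i : i + 1], np.atleast_1d(t)
            )[0]
            exact = fraction_time_above_mic(profile, 2.0, 8.0)
            assert grid_frac == pytest.approx(exact, abs=2e-4)


class TestDomainTypes:
    def test_bad_regimen_rejected(self):
        with pytest.raises(ValueError):
            DosingRegimen(dose=1000.0, tau=8.0, duration=9.0)

    def test_bad_target_fraction_rejected(self):
        with pytest.raises(ValueError):
            PTATarget(fraction=0.0)

    def test_default_mic_grid_is_twofold_ladder(self):
        g = default_mic_grid()
        assert g[0] == 0.064
        np.testing.assert_allclose(g[1:-1] / g[:-2], 2.0)
        assert g[-1] == 64.0


class TestSimulatePta:
    def test_low_mic_always_attained(self, published_model):
        res = simulate_pta(
            published_model, DosingRegimen(), 24.6, 0.40, mic_grid=[0.064],
            n_subjects=300, rng=0,
        )
        assert res.pta[0] == 100.0

    def test_monotone_in_mic_and_target(self, published_model):
        rng = np.random.default_rng(5)
        res40 = simulate_pta(published_model, DosingRegimen(), 24.6, 0.40,
                             n_subjects=300, rng=np.random.default_rng(5))
        res100 = simulate_pta(published_model, DosingRegimen(), 24.6, 1.00,
                              n_subjects=300, rng=np.random.default_rng(5))
        assert np.all(np.diff(res40.pta) <= 0)
        assert np.all(np.diff(res100.pta) <= 0)
        # stricter target cannot be easier at any MIC (shared draws)
        assert np.all(res100.pta <= res40.pta)

    def test_zero_iiv_gives_step_function(self, published_model):
        m = dataclasses.replace(published_model, iiv=IIVSpec(omega2={"V1": 0.0}))
        res = simulate_pta(m, DosingRegimen(), 24.6, 1.0, n_subjects=200, rng=0)
        assert set(np.unique(res.pta)) <= {0.0, 100.0}

    def test_longer_infusion_not_worse_near_breakpoint(self, published_model):
        shared = dict(n_subjects=2000, mic_grid=[2.0])
        p_short = simulate_pta(published_model, DosingRegimen(duration=0.5), 24.6, 1.0,
                               rng=np.random.default_rng(7), **shared)
        p_long = simulate_pta(published_model, DosingRegimen(duration=3.0), 24.6, 1.0,
                              rng=np.random.default_rng(7), **shared)
        assert p_long.pta[0] >= p_short.pta[0]

    def test_q12h_not_better_than_q8h(self, published_model):
        shared = dict(n_subjects=2000, mic_grid=[2.0])
        q8 = simulate_pta(published_model, DosingRegimen(tau=8.0), 24.6, 0.4,
                          rng=np.random.default_rng(8), **shared)
        q12 = simulate_pta(published_model, DosingRegimen(tau=12.0), 24.6, 0.4,
                           rng=np.random.default_rng(8), **shared)
        assert q12.pta[0] <= q8.pta[0]

    def test_reproducible_given_seed(self, published_model):
        a = simulate_pta(published_model, DosingRegimen(), 24.6, 0.4, n_subjects=200, rng=42)
        b = simulate_pta(published_model, DosingRegimen(), 24.6, 0.4, n_subjects=200, rng=42)
        np.testing.assert_array_equal(a.pta, b.pta)


class TestPtaVsAlbumin:
    def test_pta_decreases_with_albumin(self, published_model):
        curve = pta_vs_albumin(
            published_model, DosingRegimen(), 1.0, 2.0,
            albumin_grid=[15.6, 24.6, 31.8], n_subjects=500, rng=0,
        )
        assert curve[0] > curve[1] > curve[2]


class TestMicAtPta:
    def _result(self, pta_values, grid=None):
        from meropk.pta import PTAResult

        grid = default_mic_grid() if grid is None else np.asarray(grid)
        return PTAResult(
            mic_grid=grid, pta=np.asarray(pta_values, float),
            regimen=DosingRegimen(), target_fraction=1.0, albumin=24.6, n_subjects=1000,
        )

    def test_interpolates_in_log2(self):
        res = self._result([100.0, 80.0], grid=[1.0, 2.0])
        m = mic_at_pta(res, level=90.0)
        assert m.censored is None
        assert m.mic == pytest.approx(2.0 ** 0.5)

    def test_all_above_level_censored_high(self):
        res = self._result(np.full(11, 100.0))
        m = mic_at_pta(res)
        assert m.censored == "high" and m.mic == 64.0

    def test_never_attained_censored_low(self):
        res = self._result(np.full(11, 50.0))
        m = mic_at_pta(res)
        assert m.censored == "low" and m.mic == 0.064

    def test_multiplier_is_unity_at_breakpoint(self):
        res = self._result([95.0, 90.0, 85.0], grid=[1.0, 2.0, 4.0])
        assert dose_multiplier(res, mic_breakpoint=2.0) == pytest.approx(1.0)


class TestShiftForDose:
    def test_doubling_dose_doubles_mic_scale(self, published_model):
        res = simulate_pta(published_model, DosingRegimen(), 24.6, 0.4,
                           n_subjects=300, rng=1)
        shifted = shift_pta_for_dose(res, 2.0)
        # PTA at mic=4 under 2 g equals PTA at mic=2 under 1 g, exactly
        i = list(res.mic_grid).index(res.mic_grid[5])
        np.testing.assert_array_equal(shifted.pta, res.pta)
        np.testing.assert_allclose(shifted.mic_grid, 2.0 * res.mic_grid)
        assert shifted.regimen.dose == 2000.0

    def test_identity_at_fr_one(self, published_model):
        res = simulate_pta(published_model, DosingRegimen(), 24.6, 0.4,
                           n_subjects=300, rng=1)
        same = shift_pta_for_dose(res, 1.0)
        np.testing.assert_array_equal(same.mic_grid, res.mic_grid)

    def test_shift_equals_direct_simulation_with_shared_etas(self, published_model):
        """Dose linearity: simulated 2 g curve equals the shifted 1 g curve."""
        from meropk.pta import _draw_etas, _fractions_above, _subject_profiles

        rng_state = np.random.default_rng(9)
        etas = _draw_etas(published_model, 400, rng_state, "mc")
        times = np.linspace(0.0, 8.0, 513)
        grid = default_mic_grid()
        ptas = {}
        for dose in (1000.0, 2000.0):
            reg = DosingRegimen(dose=dose)
            conc = _subject_profiles(published_model, reg, 24.6, etas, times)
            ptas[dose] = np.array([
                100.0 * np.mean(_fractions_above(conc, times, m) >= 0.4 - 1e-12)
                for m in grid
            ])
        # PTA_2000(2*mic) == PTA_1000(mic) exactly, by linear scaling
        # (last grid point is clipped to 64 mg/l, so compare the exact ladder)
        np.testing.assert_array_equal(ptas[2000.0][1:-1], ptas[1000.0][:-2])


class TestUncertainty:
    def test_identical_sets_give_zero_width_band(self, published_model):
        res = pta_with_uncertainty(
            [published_model] * 5, DosingRegimen(), 24.6, 0.4,
            mic_grid=[1.0, 2.0], n_subjects=200, rng=3,
        )
        np.testing.assert_allclose(res.hi - res.lo, 0.0, atol=3.0)

    def test_band_widens_with_parameter_dispersion(self, published_model):
        def jittered(scale, seed):
            rng = np.random.default_rng(seed)
            out = []
            for _ in range(12):
                f = published_model.fixed
                out.append(
                    dataclasses.replace(
                        published_model,
                        fixed=dataclasses.replace(
                            f,
                            v1=f.v1 * np.exp(rng.normal(0, scale)),
                            cl_crrt=f.cl_crrt * np.exp(rng.normal(0, scale)),
                        ),
                    )
                )
            return out

        kw = dict(mic_grid=[2.0], n_subjects=300)
        narrow = pta_with_uncertainty(jittered(0.05, 1), DosingRegimen(), 24.6, 1.0,
                                      rng=5, **kw)
        wide = pta_with_uncertainty(jittered(0.4, 1), DosingRegimen(), 24.6, 1.0,
                                    rng=5, **kw)
        assert (wide.hi - wide.lo)[0] > (narrow.hi - narrow.lo)[0]
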