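"""Unit, distributional and structural tests of the latent event simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import protosim as ps
from protosim.latent import (
    NEVER,
    ADOnsetCalibration,
    reevaluation_delay_quantile,
    resolve_ad_diagnosis,
    resolve_ctcl_diagnosis,
    resolve_treatment_times,
    sample_ad_onset,
    sample_censoring_age,
    sample_ctcl_onset,
    sample_reevaluation_delay,
    sample_tcs_nonresponse_duration,
)

RNG = np.random.default_rng(20240712)


# ---------------------------------------------------------------------------
# AD onset
# ---------------------------------------------------------------------------

class TestADOnset:
    def test_non_case_draw_is_never(self):
        assert sample_ad_onset(0.50, 0.3, 0.5) == NEVER

    def test_childhood_component_inverse_cdf(self):
        # exponential with mean 3.2: onset = -3.2 * ln(0.5)
        got = sample_ad_onset(0.05, 0.20, 0.5)
        assert got == pytest.approx(3.2 * np.log(2.0), abs=1e-12)

    def test_adult_component_is_uniform_transform(self):
        got = sample_ad_onset(0.05, 0.90, 0.5)
        assert got == pytest.approx(18.0 + 0.5 * 82.0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_draws_outside_open_unit_interval_error(self, bad):
        with pytest.raises(ValueError):
            sample_ad_onset(bad, 0.5, 0.5)

    def test_marginal_anchors_at_one_million_draws(self):
        n = 1_000_000
        rng = np.random.default_rng(1)
        onset = sample_ad_onset(
            1 - rng.random(n), 1 - rng.random(n), 1 - rng.random(n)
        )
        p18 = np.mean(onset <= 18.0)
        p100 = np.mean(onset <= 100.0)
        assert 0.06 <= p18 <= 0.07
        # closed form: 0.105 * 0.63 * (1 - exp(-18/3.2)) = 0.0659
        assert p18 == pytest.approx(0.0659, abs=1e-3)
        assert 0.10 <= p100 <= 0.11
        cases = onset[onset < NEVER]
        # median among cases ~5y (closed form 5.05)
        assert np.median(cases) == pytest.approx(5.05, abs=0.15)

    def test_case_cdf_matches_closed_form(self):
        n = 1_000_000
        rng = np.random.default_rng(2)
        onset = sample_ad_onset(1 - rng.random(n), 1 - rng.random(n), 1 - rng.random(n))
        cases = onset[onset < NEVER]

        def cdf(t):
            t = np.asarray(t, dtype=float)
            childhood = 1.0 - np.exp(-t / 3.2)
            adult = np.clip((t - 18.0) / 82.0, 0.0, 1.0)
            return 0.63 * childhood + 0.37 * adult

        d = stats.ks_1samp(cases, cdf).statistic
        assert d < 0.002 * np.sqrt(n / cases.size)  # same KS bar, scaled to case count


# ---------------------------------------------------------------------------
# CTCL onset, censoring, switching, re-evaluation
# ---------------------------------------------------------------------------

class TestSimpleSamplers:
    def test_ctcl_onset_examples(self):
        assert sample_ctcl_onset(1.0, 6e-6) == 0.0
        assert sample_ctcl_onset(0.5, 6e-6) == pytest.approx(115524.5, abs=0.2)
        with pytest.raises(ValueError):
            sample_ctcl_onset(0.0, 6e-6)

    def test_ctcl_onset_tail_probability(self):
        # P(onset <= 70) = 1 - exp(-6e-6 * 70) = 4.199e-4
        n = 2_000_000
        t = sample_ctcl_onset(1 - np.random.default_rng(3).random(n), 6e-6)
        assert np.mean(t <= 70.0) == pytest.approx(4.199e-4, abs=5e-5)

    @pytest.mark.parametrize("u,expected", [(1.0, 0.0), (0.0, 100.0), (0.5, 75.0)])
    def test_censoring_boundaries(self, u, expected):
        assert sample_censoring_age(u) == pytest.approx(expected)

    def test_censoring_mean_and_cdf(self):
        u = np.random.default_rng(4).random(1_000_000)
        t = sample_censoring_age(u)
        assert np.mean(t) == pytest.approx(200.0 / 3.0, abs=0.1)
        cdf = lambda x: 1.0 - np.sqrt(np.clip(1.0 - np.asarray(x) / 100.0, 0.0, 1.0))
        assert stats.ks_1samp(t, cdf).statistic < 0.002

    def test_ctcl_onset_cdf(self):
        u = 1 - np.random.default_rng(5).random(1_000_000)
        t = sample_ctcl_onset(u, 6e-6)
        assert stats.ks_1samp(t, lambda x: -np.expm1(-6e-6 * np.asarray(x))).statistic < 0.002

    @pytest.mark.parametrize(
        "w,u4,e1,expected", [(0, 0.5, 0.0, 0.75), (1, 0.0, 0.3, 1.3), (0, 1.0, 0.0, 0.0)]
    )
    def test_tcs_nonresponse_examples(self, w, u4, e1, expected):
        assert sample_tcs_nonresponse_duration(w, u4, e1) == pytest.approx(expected)

    def test_tcs_nonresponse_branch_ranges(self):
        rng = np.random.default_rng(6)
        short = sample_tcs_nonresponse_duration(0, rng.random(10_000), rng.exponential(1 / 3, 10_000))
        long = sample_tcs_nonresponse_duration(1, rng.random(10_000), rng.exponential(1 / 3, 10_000))
        assert np.all(short <= 1.0)
        assert np.all(long >= 1.0)

    def test_reevaluation_median_closed_form(self):
        # max of two Weibull(shape 0.9, scale 3.5): median 4.40y,
        # and with a single draw the lower quartile machinery gives 2.33y
        assert reevaluation_delay_quantile(0.5, 3.5) == pytest.approx(4.40, abs=0.005)
        assert reevaluation_delay_quantile(0.5, 3.5, n_draws=1) == pytest.approx(2.33, abs=0.005)
        assert reevaluation_delay_quantile(0.25, 3.5) == pytest.approx(
            reevaluation_delay_quantile(0.5, 3.5, n_draws=1)
        )

    def test_reevaluation_delay_sampler(self):
        assert sample_reevaluation_delay(np.array([0.0, 0.0]), 3.5) == 0.0
        u = np.random.default_rng(7).random((1_000_000, 2))
        s2 = sample_reevaluation_delay(u, 3.5, 0.9)
        assert np.median(s2) == pytest.approx(4.40, abs=0.05)
        cdf = lambda x: (1.0 - np.exp(-((np.asarray(x, dtype=float) / 3.5) ** 0.9))) ** 2
        assert stats.ks_1samp(s2, cdf).statistic < 0.002


# ---------------------------------------------------------------------------
# Resolution logic
# ---------------------------------------------------------------------------

class TestResolution:
    @pytest.mark.parametrize(
        "t_ad,t_ctcl,q,expected",
        [(30, 50, 0, 30), (30, 50, 1, 30), (90, 50, 0, 50), (90, 50, 1, 90)],
    )
    def test_ad_diagnosis(self, t_ad, t_ctcl, q, expected):
        assert resolve_ad_diagnosis(t_ad, t_ctcl, q) == expected

    @given(
        t_ad=st.floats(0, 1e9), t_ctcl=st.floats(0, 1e7), q=st.integers(0, 1)
    )
    @settings(deadline=None, derandomize=True)
    def test_ad_diagnosis_properties(self, t_ad, t_ctcl, q):
        obs = float(resolve_ad_diagnosis(t_ad, t_ctcl, q))
        assert obs in (t_ad, t_ctcl)
        assert obs >= min(t_ad, t_ctcl)

    def test_treatment_times_tcs_switcher(self):
        t_tcs, t_tacro1, t_tacro = resolve_treatment_times(
            t_ad_obs=4.0, t_ad=4.0, t_ctcl=80.0, t_cens=70.0,
            s=1, p_switch=1, r_switch=0, s1=0.5,
        )
        assert (t_tcs, t_tacro1, t_tacro) == (4.0, 70.0, 4.5)

    def test_treatment_times_misdiagnosed_non_switcher(self):
        t_tcs, _, t_tacro = resolve_treatment_times(
            t_ad_obs=50.0, t_ad=90.0, t_ctcl=50.0, t_cens=80.0,
            s=1, p_switch=1, r_switch=0, s1=0.5,
        )
        assert t_tcs == 50.0
        assert t_tacro == 80.0  # never within lifetime

    def test_treatment_times_first_line_tacrolimus(self):
        t_tcs, t_tacro1, t_tacro = resolve_treatment_times(
            t_ad_obs=20.0, t_ad=20.0, t_ctcl=90.0, t_cens=70.0,
            s=0, p_switch=0, r_switch=0, s1=0.5,
        )
        assert t_tacro == t_tacro1 == 20.0
        assert t_tcs == 70.0

    @pytest.mark.parametrize(
        "t_ad_obs,t_ad,t_ctcl,s2,expected",
        [(30, 30, 50, 4.4, 50.0), (50, 90, 50, 4.4, 54.4), (50, 90, 50, 0.0, 50.0)],
    )
    def test_ctcl_diagnosis(self, t_ad_obs, t_ad, t_ctcl, s2, expected):
        assert resolve_ctcl_diagnosis(t_ad_obs, t_ad, t_ctcl, s2) == expected


# ---------------------------------------------------------------------------
# Whole-population structure
# ---------------------------------------------------------------------------

class TestSimulatePopulation:
    def test_determinism(self, a1_small):
        small = a1_small.replace(base_population=50_000)
        a = ps.simulate_population(small, seed=99)
        b = ps.simulate_population(small, seed=99)
        for name in ("t_ad", "t_ctcl", "t_cens", "s1", "s2", "t_tacro", "t_ctcl_obs"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))
        c = ps.simulate_population(small, seed=100)
        assert not np.array_equal(a.t_ad, c.t_ad)

    def test_structural_invariants(self, small_population):
        pop = small_population
        assert np.all(pop.t_cens <= 100.0)
        assert np.all(pop.t_ad >= 0) and np.all(pop.t_ctcl >= 0)
        # diagnosis is one of the onsets and never precedes both
        assert np.all((pop.t_ad_obs == pop.t_ad) | (pop.t_ad_obs == pop.t_ctcl))
        assert np.all(pop.t_ad_obs >= np.minimum(pop.t_ad, pop.t_ctcl))
        # CTCL diagnosis never precedes onset; equality iff not misdiagnosed
        assert np.all(pop.t_ctcl_obs >= pop.t_ctcl)
        misdx = pop.t_ad_obs == pop.t_ctcl
        misdx &= pop.t_ad_obs != pop.t_ad
        np.testing.assert_allclose(
            pop.t_ctcl_obs[misdx], pop.t_ad_obs[misdx] + pop.s2[misdx]
        )
        assert np.all(pop.t_ctcl_obs[~misdx] == pop.t_ctcl[~misdx])
        # misdiagnosis requires CTCL-first and q=0
        assert np.all(pop.t_ctcl[misdx] <= pop.t_ad[misdx])
        assert np.all(pop.q[misdx] == 0)
        # switch-duration components
        assert np.all(pop.s1[pop.w == 0] <= 1.0)
        assert np.all(pop.s1[pop.w == 1] >= 1.0)
        # treatment-time identities (restricted to diagnosed patients)
        dx = pop.t_ad_obs < ps.NEVER
        first_line_tacro = dx & (pop.s == 0)
        assert np.all(pop.t_tacro[first_line_tacro] == pop.t_ad_obs[first_line_tacro])
        assert np.all(pop.t_tcs[first_line_tacro] == pop.t_cens[first_line_tacro])
        switch_flag = np.where(misdx, pop.r_switch, pop.p_switch)
        non_switch = dx & (pop.s == 1) & (switch_flag == 0)
        assert np.all(pop.t_tacro[non_switch] == pop.t_cens[non_switch])
        # status flags
        np.testing.assert_array_equal(pop.status_ctcl, (pop.t_ctcl_obs < pop.t_cens))

    def test_correctly_diagnosed_ctcl_first_never_treated_before_outcome(
        self, small_population
    ):
        # q=1 patients whose CTCL precedes AD onset are diagnosed with CTCL
        # at onset; any later AD diagnosis can never start before it.
        pop = small_population
        m = (pop.q == 1) & (pop.t_ctcl <= pop.t_ad)
        assert np.all(pop.t_ctcl_obs[m] == pop.t_ctcl[m])
        assert np.all(pop.t_ad_obs[m] >= pop.t_ctcl_obs[m])

    def test_p1_equal_one_switches_off_misdiagnosis(self, a1_small):
        params = a1_small.replace(setting_id="null-p1", p1=1.0, base_population=100_000)
        pop = ps.simulate_population(params, seed=11)
        misdx = (pop.t_ad_obs == pop.t_ctcl) & (pop.t_ctcl < pop.t_ad)
        assert not misdx.any()
        assert np.all(pop.t_ctcl_obs == pop.t_ctcl)

    def test_lifetime_ctcl_count_scales_with_rate(self, a1_small):
        # expectation n * lambda * E[t_cens] = n * 6e-6 * 200/3
        params = a1_small.replace(base_population=1_000_000)
        pop = ps.simulate_population(params, seed=12)
        count = int(np.sum(pop.t_ctcl < pop.t_cens))
        expected = 1_000_000 * 6e-6 * 200.0 / 3.0
        assert abs(count - expected) < 3 * np.sqrt(expected)

    def test_to_frame_serialises_never_as_missing(self, a1_small):
        pop = ps.simulate_population(a1_small.replace(base_population=5_000), seed=13)
        df = pop.to_frame()
        assert df.loc[df["t_ad"].isna()].shape[0] == int(np.sum(pop.t_ad >= ps.NEVER))
        assert df["t_ctcl"].notna().all()
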