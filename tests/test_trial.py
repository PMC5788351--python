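"""Monte-Carlo trial engine against deterministic forecasting oracles."""

import numpy as np
import pytest

from admarkov import (
    DiseaseState,
    InvalidParameterError,
    TransitionParamTable,
    TreatmentSpec,
    TrialConfig,
    TrialOutcome,
    apply_treatment,
    run_trial,
    secondary_endpoints,
    summarize,
)

CN, MCI, AD, W = DiseaseState


def forecast(step_matrix, start, n_steps):
    """Independent matrix-power forecast of state occupancy."""
    dist = np.zeros(4)
    dist[start] = 1.0
    out = [dist]
    for _ in range(n_steps):
        dist = dist @ step_matrix
        out.append(dist)
    return np.array(out)


def monthly_step(table: TransitionParamTable) -> np.ndarray:
    """Step matrix built independently of the package conversion helper."""
    annual = table.mean_matrix()
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j and annual[i, j] > 0:
                q[i, j] = 1 - (1 - annual[i, j]) ** (1 / 12)
    for i in range(4):
        q[i, i] = 1 - q[i].sum()
    return q


class TestApplyTreatment:
    def test_null_treatment_is_identity(self, zero_sd_table):
        from admarkov import draw_individual_probs

        m = draw_individual_probs(zero_sd_table, 0)
        out = apply_treatment(m, TreatmentSpec(e_cn_mci=0.0, e_mci_ad=0.0))
        np.testing.assert_array_equal(out, m)

    def test_full_efficacy_blocks_edge_and_recloses(self, zero_sd_table):
        from admarkov import draw_individual_probs

        m = draw_individual_probs(zero_sd_table, 0)
        out = apply_treatment(m, TreatmentSpec(e_mci_ad=1.0))
        assert out[MCI, AD] == 0.0
        assert out[MCI, MCI] == pytest.approx(m[MCI, MCI] + 0.0954, abs=1e-12)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_half_efficacy_halves_probability(self, zero_sd_table):
        from admarkov import draw_individual_probs

        m = draw_individual_probs(zero_sd_table, 0)
        out = apply_treatment(m, TreatmentSpec(e_cn_mci=0.5))
        assert out[CN, MCI] == pytest.approx(0.0432 * 0.5, abs=1e-15)

    def test_before_delay_unchanged(self, zero_sd_table):
        from admarkov import draw_individual_probs

        m = draw_individual_probs(zero_sd_table, 0)
        spec = TreatmentSpec(e_cn_mci=0.8, delay_months=24)
        np.testing.assert_array_equal(apply_treatment(m, spec, current_month=12), m)
        assert apply_treatment(m, spec, current_month=24)[CN, MCI] < m[CN, MCI]

    def test_efficacy_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            TreatmentSpec(e_cn_mci=1.5)
        with pytest.raises(InvalidParameterError):
            TreatmentSpec(e_mci_ad=-0.1)


class TestRunTrial:
    def test_conservation_of_individuals(self, default_table):
        out = run_trial(
            TrialConfig(n_individuals=200, duration_months=36, realisations=20,
                        table=default_table, seed=4)
        )
        assert (out.counts.sum(axis=2) == 200).all()

    def test_full_cn_mci_block_prevents_ad(self, zero_sd_table):
        out = run_trial(
            TrialConfig(
                n_individuals=300, duration_months=60, realisations=50,
                treatment=TreatmentSpec(e_cn_mci=1.0), table=zero_sd_table, seed=1,
            )
        )
        assert (out.counts[:, :, AD] == 0).all()

    def test_zero_efficacy_reproduces_untreated_exactly(self, default_table):
        base = TrialConfig(n_individuals=200, duration_months=36, realisations=30,
                           table=default_table, seed=7)
        treated = TrialConfig(
            n_individuals=200, duration_months=36, realisations=30,
            treatment=TreatmentSpec(e_cn_mci=0.0, e_mci_ad=0.0),
            table=default_table, seed=7,
        )
        np.testing.assert_array_equal(run_trial(base).counts, run_trial(treated).counts)

    def test_all_ad_start_matches_annual_withdrawal_split(self, zero_sd_table):
        """Mean AD proportion at month 12 ≈ annual AD survival 0.8235."""
        out = run_trial(
            TrialConfig(
                n_individuals=500, duration_months=12, realisations=400,
                initial_composition={"AD": 1.0}, table=zero_sd_table, seed=2,
            )
        )
        mean_ad = out.mean_proportion(AD)[-1]
        se = np.sqrt(0.8235 * (1 - 0.8235) / (500 * 400))
        assert abs(mean_ad - 0.8235) < 3 * se

    def test_occupancy_matches_matrix_power_oracle(self, zero_sd_table):
        """Zero-SD trajectories track the deterministic forecast everywhere."""
        N, R, T = 400, 400, 24
        out = run_trial(
            TrialConfig(n_individuals=N, duration_months=T, realisations=R,
                        table=zero_sd_table, seed=3)
        )
        expect = forecast(monthly_step(zero_sd_table), CN, T)
        mean = out.proportions.mean(axis=0)
        for s in range(4):
            p = expect[:, s]
            tol = 3 * np.sqrt(np.maximum(p * (1 - p), 0.0) / (N * R))
            assert (np.abs(mean[:, s] - p) <= tol + 1e-12).all(), s

    def test_delay_blocks_treatment_until_activation(self, zero_sd_table):
        """With CN→MCI fully blocked after month 6, MCI onset stops there."""
        out = run_trial(
            TrialConfig(
                n_individuals=300, duration_months=24, realisations=10,
                treatment=TreatmentSpec(e_cn_mci=1.0, delay_months=6),
                table=zero_sd_table, seed=5, track_individuals=True,
            )
        )
        # MCI can only be entered from CN; first MCI entries all at/before month 6
        assert out.reach_fraction[:, MCI].max() > 0  # some conversions pre-delay
        fp = out.first_passage_mean[:, MCI]
        assert np.nanmax(fp) <= 6.0

    def test_delay_beyond_horizon_equals_untreated(self, default_table):
        base = TrialConfig(n_individuals=150, duration_months=24, realisations=20,
                           table=default_table, seed=9)
        delayed = TrialConfig(
            n_individuals=150, duration_months=24, realisations=20,
            treatment=TreatmentSpec(e_cn_mci=0.9, e_mci_ad=0.9, delay_months=24),
            table=default_table, seed=9,
        )
        np.testing.assert_array_equal(
            run_trial(base).counts, run_trial(delayed).counts
        )


class TestSummarize:
    @staticmethod
    def outcome_from_ad_counts(values, n=1000):
        R = len(values)
        counts = np.zeros((R, 1, 4), dtype=np.int32)
        counts[:, 0, AD] = values
        counts[:, 0, CN] = n - np.asarray(values)
        return TrialOutcome(
            times_months=np.array([0]), counts=counts, n_individuals=n, seed=0
        )

    def test_constant_realisations_degenerate_interval(self):
        out = self.outcome_from_ad_counts([100, 100, 100])
        summ = summarize(out)
        ad = summ[summ["state"] == "AD"].iloc[0]
        assert ad["mean"] == pytest.approx(0.1, abs=1e-15)
        assert ad["sd"] == pytest.approx(0.0, abs=1e-15)
        assert ad["ci_lo"] == 0.1 and ad["ci_hi"] == 0.1

    def test_two_point_distribution_hits_extremes(self):
        out = self.outcome_from_ad_counts([0, 1000])
        ad = summarize(out).query("state == 'AD'").iloc[0]
        assert ad["mean"] == 0.5
        assert ad["ci_lo"] == 0.0 and ad["ci_hi"] == 1.0

    def test_interval_matches_binomial_quantile_oracle(self):
        from scipy import stats

        n, p, R = 1000, 0.1, 4000
        rng = np.random.default_rng(12)
        values = rng.binomial(n, p, R)
        ad = summarize(self.outcome_from_ad_counts(values, n)).query(
            "state == 'AD'"
        ).iloc[0]
        for level, key in ((0.025, "ci_lo"), (0.975, "ci_hi")):
            k = stats.binom.ppf(level, n, p)
            density = stats.binom.pmf(k, n, p) * n  # density on proportion scale
            tol = 3 * np.sqrt(level * (1 - level) / R) / density
            assert abs(ad[key] - k / n) <= tol + 1.0 / n


class TestSecondaryEndpoints:
    def test_requires_tracking(self, default_table):
        out = run_trial(TrialConfig(n_individuals=50, duration_months=12,
                                    realisations=3, table=default_table, seed=0))
        with pytest.raises(InvalidParameterError, match="track_individuals"):
            secondary_endpoints(out)

    def test_static_chain_spends_horizon_in_baseline(self):
        table = TransitionParamTable.from_means({})
        out = run_trial(
            TrialConfig(n_individuals=50, duration_months=36, realisations=5,
                        table=table, seed=1, track_individuals=True)
        )
        ep = secondary_endpoints(out)
        assert ep.incidence_ad == 0.0
        assert ep.mean_months_in_state["CN"] == 36.0
        assert ep.reach_probability["AD"] == 0.0

    def test_forced_two_step_path_first_passage(self):
        table = TransitionParamTable.from_means(
            {(CN, MCI): 1.0, (MCI, AD): 1.0}
        )
        out = run_trial(
            TrialConfig(n_individuals=20, duration_months=6, realisations=3,
                        table=table, seed=2, track_individuals=True)
        )
        ep = secondary_endpoints(out)
        assert ep.mean_first_passage_month["MCI"] == 1.0
        assert ep.mean_first_passage_month["AD"] == 2.0
        assert ep.incidence_ad == 1.0

    def test_against_absorbing_chain_oracle(self, zero_sd_table):
        """Incidence, occupancy and first passage vs finite-horizon chain maths."""
        N, R, T = 400, 300, 60
        out = run_trial(
            TrialConfig(n_individuals=N, duration_months=T, realisations=R,
                        table=zero_sd_table, seed=6, track_individuals=True)
        )
        ep = secondary_endpoints(out)
        step = monthly_step(zero_sd_table)

        # oracle 1: occupancy integral of the forecast
        occ = forecast(step, CN, T)[:-1].sum(axis=0)
        for k, s in enumerate(("CN", "MCI", "AD", "WITHDRAWN")):
            se = out.months_in_state[:, k].std(ddof=1) / np.sqrt(R)
            assert abs(ep.mean_months_in_state[s] - occ[k]) < 3 * se + 1e-9, s

        # oracle 2: make AD absorbing; its mass at t = P(reached AD by t)
        absorbing = step.copy()
        absorbing[AD] = np.eye(4)[AD]
        reach = forecast(absorbing, CN, T)[:, AD]
        se = out.incidence.std(ddof=1) / np.sqrt(R)
        assert abs(ep.incidence_ad - reach[-1]) < 3 * se

        # oracle 3: mean first-passage month among reachers
        f = np.diff(reach)  # P(first reach at month t+1)
        mean_fp = (np.arange(1, T + 1) * f).sum() / f.sum()
        fp = out.first_passage_mean[:, AD]
        fp = fp[~np.isnan(fp)]
        se = fp.std(ddof=1) / np.sqrt(len(fp))
        assert abs(ep.mean_first_passage_month["AD"] - mean_fp) < 3 * se + 0.5
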