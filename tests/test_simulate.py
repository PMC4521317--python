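"""Synthetic ICU cohort generator: determinism, structure, default panel."""

import numpy as np
import pandas as pd
import pytest

from icuinfo.preprocess import daily_median
from icuinfo.simulate import CohortConfig, VariableSpec, default_icu_specs, generate_cohort


def _two_var_config(rho=0.9, **kwargs):
    specs = [
        VariableSpec("a", "normal", 0.0, 1.0, temporal_rho=0.5),
        VariableSpec("b", "normal", 0.0, 1.0, temporal_rho=0.5),
    ]
    corr = np.array([[1.0, rho], [rho, 1.0]])
    defaults = dict(n_patients=5000, n_days=1, cross_correlation=corr, attrition=(1.0,), seed=3)
    defaults.update(kwargs)
    return specs, CohortConfig(**defaults)


class TestContracts:
    def test_empty_cohort(self):
        specs, config = _two_var_config(n_patients=0)
        assert generate_cohort(config, specs).empty

    def test_same_seed_identical_output(self):
        specs, config = default_icu_specs(n_patients=200, seed=7)
        a = generate_cohort(config, specs)
        b = generate_cohort(config, specs)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seed_differs(self):
        specs, _ = default_icu_specs(n_patients=200, seed=7)
        _, c7 = default_icu_specs(n_patients=200, seed=7)
        _, c8 = default_icu_specs(n_patients=200, seed=8)
        assert not generate_cohort(c7, specs).equals(generate_cohort(c8, specs))

    def test_non_psd_correlation_rejected_with_eigenvalue(self):
        specs = [
            VariableSpec(n, "normal", 0.0, 1.0) for n in ("a", "b", "c")
        ]
        corr = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        config = CohortConfig(n_patients=10, n_days=1, cross_correlation=corr, attrition=(1.0,))
        with pytest.raises(ValueError, match="eigenvalue"):
            generate_cohort(config, specs)

    def test_bad_measurement_range_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=5, measurements_per_day=(4, 1))

    def test_sorted_output_and_columns(self):
        specs, config = default_icu_specs(n_patients=50, seed=1)
        obs = generate_cohort(config, specs)
        assert list(obs.columns) == ["patient_id", "day", "variable", "value"]
        key = obs[["patient_id", "day", "variable"]].apply(tuple, axis=1)
        assert key.is_monotonic_increasing


class TestStructure:
    def test_cross_correlation_recovered(self):
        specs, config = _two_var_config(rho=0.9)
        daily = daily_median(generate_cohort(config, specs))
        wide = daily.pivot_table(index="patient_id", columns="variable", values="value")
        r = wide["a"].corr(wide["b"])
        assert 0.85 <= r <= 0.95

    def test_coupling_monotone_in_configured_correlation(self):
        observed = []
        for rho in (0.0, 0.5, 0.9):
            specs, config = _two_var_config(rho=rho, seed=11)
            daily = daily_median(generate_cohort(config, specs))
            wide = daily.pivot_table(index="patient_id", columns="variable", values="value")
            observed.append(wide["a"].corr(wide["b"]))
        assert observed[0] < observed[1] < observed[2]

    def test_attrition_is_monotone_dropout(self, default_cohort):
        obs, _, _ = default_cohort
        patients_by_day = {
            day: set(obs.loc[obs["day"] == day, "patient_id"]) for day in (1, 2, 3)
        }
        assert patients_by_day[3] <= patients_by_day[2] <= patients_by_day[1]

    def test_attrition_rates_near_defaults(self, default_cohort):
        obs, _, config = default_cohort
        n1 = obs.loc[obs["day"] == 1, "patient_id"].nunique()
        n2 = obs.loc[obs["day"] == 2, "patient_id"].nunique()
        n3 = obs.loc[obs["day"] == 3, "patient_id"].nunique()
        assert n2 / n1 == pytest.approx(0.68, abs=0.05)
        assert n3 / n1 == pytest.approx(0.46, abs=0.05)

    def test_measurements_per_day_in_range(self, default_cohort):
        obs, _, config = default_cohort
        counts = obs.groupby(["patient_id", "day", "variable"], observed=True).size()
        lo, hi = config.measurements_per_day
        assert counts.min() >= lo and counts.max() <= hi

    def test_daily_median_recovers_latent_exactly(self):
        # noise draws are median-centred, so the median equals the latent value
        specs = [VariableSpec("a", "normal", 10.0, 2.0, noise_sd=0.5)]
        config = CohortConfig(n_patients=100, n_days=1, attrition=(1.0,), seed=5)
        obs = generate_cohort(config, specs)
        noiseless = generate_cohort(
            config, [VariableSpec("a", "normal", 10.0, 2.0, noise_sd=0.0)]
        )
        med = daily_median(obs).set_index("patient_id")["value"]
        ref = daily_median(noiseless).set_index("patient_id")["value"]
        pd.testing.assert_series_equal(med, ref)


class TestDefaultPanel:
    def test_eleven_variables_with_expected_families(self):
        specs, _ = default_icu_specs()
        assert len(specs) == 11
        families = {s.name: s.marginal_family for s in specs}
        for name in ("platelet", "wbc", "glucose", "bun", "creatinine", "lactate"):
            assert families[name] == "lognormal"
        for name in ("hematocrit", "hco3", "potassium", "sodium", "chloride"):
            assert families[name] == "normal"

    def test_lognormal_values_positive(self, default_cohort):
        obs, specs, _ = default_cohort
        lognormal = {s.name for s in specs if s.marginal_family == "lognormal"}
        assert (obs.loc[obs["variable"].isin(lognormal), "value"] > 0).all()

    def test_day1_sodium_mean(self, default_cohort):
        obs, _, _ = default_cohort
        d1 = daily_median(obs).query("day == 1 and variable == 'sodium'")["value"]
        assert d1.mean() == pytest.approx(138.6, abs=2.0)

    def test_day1_creatinine_sd(self, default_cohort):
        obs, _, _ = default_cohort
        d1 = daily_median(obs).query("day == 1 and variable == 'creatinine'")["value"]
        assert d1.std() == pytest.approx(1.5, abs=0.5)

    def test_day1_moments_within_20_percent_of_targets(self, default_cohort):
        obs, specs, _ = default_cohort
        daily = daily_median(obs).query("day == 1")
        for spec in specs:
            mean_t, sd_t = spec.implied_moments()
            values = daily.loc[daily["variable"] == spec.name, "value"]
            assert abs(values.mean() - mean_t) <= 0.2 * mean_t, spec.name
            assert abs(values.std() - sd_t) <= 0.2 * sd_t, spec.name

    def test_lactate_is_least_measured(self, default_cohort):
        obs, _, _ = default_cohort
        counts = obs.groupby("variable", observed=True)["patient_id"].nunique()
        assert counts.idxmin() == "lactate"

    def test_coupling_defaults(self):
        specs, config = default_icu_specs()
        names = [s.name for s in specs]
        corr = config.cross_correlation
        get = lambda a, b: corr[names.index(a), names.index(b)]
        assert get("creatinine", "bun") >= 0.7
        assert get("sodium", "chloride") >= 0.7
        assert get("hco3", "lactate") < 0
        assert 0 < get("wbc", "platelet") <= 0.2
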