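"""Linear, additive and mixed-effects model behaviour."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import compbias as cb
from compbias.errors import ContractViolation, DegenerateModelError
from conftest import grouped_regression_data


def simple_gam_data(seed=0, n=400, f=lambda x: 2 * x, noise=0.2):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    y = f(x) + rng.normal(0, noise, n)
    return pd.DataFrame({"genome_id": [f"g{i}" for i in range(n)], "x": x, "y": y})


class TestFitGam:
    def test_linear_truth_recovery(self):
        data = simple_gam_data(seed=1)
        fit = cb.fit_gam(cb.ModelSpec(response="y", smooth_terms=[("x", 10)]), data)
        assert fit.smooths["x"].edf < 1.5  # effectively linear
        est, se = fit.fixed.loc["x", ["estimate", "se"]]
        assert abs(est - 2.0) < 2 * se
        assert fit.converged

    def test_sine_truth_mse_bound(self):
        data = simple_gam_data(seed=2, n=2000, f=lambda x: np.sin(2 * np.pi * x), noise=0.1)
        fit = cb.fit_gam(cb.ModelSpec(response="y", smooth_terms=[("x", 10)]), data)
        grid = fit.smooths["x"].curve
        truth = np.sin(2 * np.pi * grid["x"]) - np.mean(np.sin(2 * np.pi * data["x"]))
        mse = float(np.mean((grid["fit"] - truth) ** 2))
        assert mse < 2 * 0.01 * fit.edf_total / 2000

    def test_constant_response_gives_flat_smooth(self):
        data = simple_gam_data(seed=3)
        data["y"] = 1.0
        fit = cb.fit_gam(cb.ModelSpec(response="y", smooth_terms=[("x", 10)]), data)
        assert np.abs(fit.smooths["x"].curve["fit"]).max() < 1e-6

    def test_penalty_limits(self):
        """Penalty -> infinity reproduces the OLS line; penalty -> 0 fits the
        data more closely than the heavily penalized fit."""
        data = simple_gam_data(seed=4, f=lambda x: np.sin(2 * np.pi * x), noise=0.1)
        spec = cb.ModelSpec(response="y", smooth_terms=[("x", 10)])
        stiff = cb.fit_gam(spec, data, fixed_loggamma=np.array([-12.0]))
        slope, intercept = np.polyfit(data["x"], data["y"], 1)
        assert stiff.fixed.loc["x", "estimate"] == pytest.approx(slope, rel=1e-3)
        assert stiff.fixed.loc["(Intercept)", "estimate"] == pytest.approx(intercept, rel=1e-3, abs=1e-3)
        wiggly = cb.fit_gam(spec, data, fixed_loggamma=np.array([12.0]))
        assert (wiggly.residuals**2).sum() < (stiff.residuals**2).sum()

    def test_residual_mean_zero_diagnostic(self):
        data = simple_gam_data(seed=5, n=1000)
        fit = cb.fit_gam(cb.ModelSpec(response="y", smooth_terms=[("x", 10)]), data)
        std = fit.residuals / np.sqrt(fit.sigma2)
        assert abs(std.mean()) < 3 / np.sqrt(fit.n_obs)

    def test_mgcv_cross_check(self):
        """Independent oracle: mgcv's REML cubic-spline GAM on the same data
        produces an equivalent fitted function."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        data = simple_gam_data(seed=6, n=300, f=lambda x: np.sin(2 * np.pi * x), noise=0.1)
        fit = cb.fit_gam(cb.ModelSpec(response="y", smooth_terms=[("x", 10)]), data)
        script = (
            "suppressMessages(library(mgcv));"
            "d <- read.csv('data.csv');"
            "m <- gam(y ~ s(x, k=10, bs='cr'), data=d, method='REML');"
            "write.csv(data.frame(f=fitted(m)), 'fit.csv', row.names=FALSE)"
        )
        import tempfile, os
        with tempfile.TemporaryDirectory() as td:
            data[["x", "y"]].to_csv(os.path.join(td, "data.csv"), index=False)
            subprocess.run(["Rscript", "-e", script], cwd=td, check=True,
                           capture_output=True)
            r_fitted = pd.read_csv(os.path.join(td, "fit.csv"))["f"].to_numpy()
        rmse = float(np.sqrt(np.mean((fit.fitted - r_fitted) ** 2)))
        assert rmse < 0.05  # half the noise SD; both track the same curve


class TestFitGamm:
    def test_null_cluster_effects_estimated_near_zero(self):
        data, tax = grouped_regression_data(seed=0, m_groups=30, n_per=200)
        spec = cb.ModelSpec(
            response="y", smooth_terms=[("x", 10)],
            random_structure=cb.RandomStructure(levels=("phylum",), slope_on="x"),
        )
        fit = cb.fit_gamm(spec, data, tax)
        assert fit.random_sd["var_ratio"].max() < 0.01

    def test_slope_sd_recovery(self):
        data, tax = grouped_regression_data(
            seed=1, m_groups=30, n_per=10, intercept_sd=0.3, slope_sd=0.5
        )
        spec = cb.ModelSpec(
            response="y", smooth_terms=[("x", 10)],
            random_structure=cb.RandomStructure(levels=("phylum",), slope_on="x"),
        )
        fit = cb.fit_gamm(spec, data, tax)
        sd = float(fit.random_sd.query("kind == 'slope'")["sd"].iloc[0])
        assert 0.3 <= sd <= 0.7

    def test_fixed_linear_coefficient_recovery(self):
        data, tax = grouped_regression_data(
            seed=2, m_groups=20, n_per=15, intercept_sd=0.3, fixed_linear=1.0
        )
        spec = cb.ModelSpec(
            response="y", linear_terms=["z"], smooth_terms=[("x", 10)],
            random_structure=cb.RandomStructure(levels=("phylum",), slope_on="x"),
        )
        fit = cb.fit_gamm(spec, data, tax)
        est, se = fit.fixed.loc["z", ["estimate", "se"]]
        assert est > 0
        assert abs(est - 1.0) < 2 * se

    def test_group_relabelling_invariance(self):
        data, tax = grouped_regression_data(seed=3, m_groups=10, n_per=12,
                                            intercept_sd=0.4, slope_sd=0.3)
        spec = cb.ModelSpec(
            response="y", smooth_terms=[("x", 10)],
            random_structure=cb.RandomStructure(levels=("phylum",), slope_on="x"),
        )
        fit1 = cb.fit_gamm(spec, data, tax)
        relabel = {f"P{i:02d}": f"Q{9 - i}" for i in range(10)}
        tax2 = tax.assign(
            phylum=tax["phylum"].map(relabel), genus=tax["genus"].map(relabel),
            species=tax["species"].map(relabel),
        )
        fit2 = cb.fit_gamm(spec, data, tax2)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-5)
        np.testing.assert_allclose(
            np.sort(fit1.random_sd["sd"]), np.sort(fit2.random_sd["sd"]), rtol=1e-4, atol=1e-8
        )

    def test_mixedlm_cross_check(self):
        """statsmodels MixedLM is an independent oracle for the pure
        random-intercept special case."""
        import statsmodels.formula.api as smf

        data, tax = grouped_regression_data(seed=4, m_groups=25, n_per=12,
                                            intercept_sd=0.7, noise_sd=0.4)
        data = data.assign(phylum=tax["phylum"].to_numpy())
        spec = cb.ModelSpec(
            response="y", linear_terms=["x"],
            random_structure=cb.RandomStructure(levels=("phylum",), slope_on="x",
                                                slopes=False),
        )
        fit = cb.fit_gamm(spec, data, tax)
        ml = smf.mixedlm("y ~ x", data, groups=data["phylum"]).fit(reml=True)
        assert fit.sigma2 == pytest.approx(float(ml.scale), rel=1e-4)
        tau2 = float(fit.random_sd["sd"].iloc[0]) ** 2
        assert tau2 == pytest.approx(float(ml.cov_re.iloc[0, 0]), rel=1e-3)
        np.testing.assert_allclose(
            fit.fixed["estimate"].to_numpy(), ml.fe_params.to_numpy(), rtol=1e-5
        )

    def test_taxonomy_must_cover_genomes(self):
        data, tax = grouped_regression_data(seed=5, m_groups=4, n_per=5)
        spec = cb.ModelSpec(
            response="y", smooth_terms=[("x", 10)],
            random_structure=cb.RandomStructure(levels=("phylum",), slope_on="x"),
        )
        with pytest.raises(ContractViolation):
            cb.fit_gamm(spec, data, tax.iloc[:-2])

    def test_single_group_degenerate(self):
        data, tax = grouped_regression_data(seed=6, m_groups=1, n_per=20)
        spec = cb.ModelSpec(
            response="y", smooth_terms=[("x", 10)],
            random_structure=cb.RandomStructure(levels=("phylum",), slope_on="x"),
        )
        with pytest.raises(DegenerateModelError):
            cb.fit_gamm(spec, data, tax)


class TestAtOnCodons:
    def _profiles(self, n=120, seed=0):
        cohort = cb.simulate_cohort(
            cb.CohortConfig(n_phyla=30, genera_per_phylum=2, species_per_genus=2,
                            n_codons_per_genome=4000, seed=seed)
        )
        from compbias.pipeline import profiles_to_frame

        profs, mets = cohort.profiles()
        return profiles_to_frame(profs, mets)

    def test_generator_at_is_linear_in_codons(self):
        fit = cb.fit_at_on_codons(self._profiles())
        assert fit.r_squared > 0.95
        assert fit.coefficients["aliased"].sum() >= 1  # compositional collinearity

    def test_signal_exceeds_permutation_null(self):
        """The real %AT response gives R^2 above the 95th percentile of the
        permutation null, which stays well below it (n = 500)."""
        cohort = cb.simulate_cohort(
            cb.CohortConfig(n_phyla=25, genera_per_phylum=5, species_per_genus=4,
                            n_codons_per_genome=2000, seed=5)
        )
        from compbias.pipeline import profiles_to_frame

        profs, mets = cohort.profiles()
        profiles = profiles_to_frame(profs, mets)
        real = cb.fit_at_on_codons(profiles).r_squared
        rng = np.random.default_rng(2)
        shuffled = profiles.copy()
        null_r2 = []
        for _ in range(30):
            shuffled["at_fraction"] = rng.permutation(profiles["at_fraction"].to_numpy())
            null_r2.append(cb.fit_at_on_codons(shuffled).r_squared)
        assert real > np.quantile(null_r2, 0.95)
        assert np.quantile(null_r2, 0.95) < 0.5

    def test_too_few_genomes_raises(self):
        profiles = self._profiles().iloc[:40]
        with pytest.raises(DegenerateModelError):
            cb.fit_at_on_codons(profiles)


class TestAnovaAaubPhylum:
    def _tax(self, phyla):
        gids = [f"g{i}" for i in range(len(phyla))]
        return pd.DataFrame(
            {"genome_id": gids, "phylum": phyla, "genus": phyla,
             "species": phyla, "strain": gids}
        )

    def test_saturated_two_phylum_case(self):
        phyla = ["A"] * 3 + ["B"] * 3
        tax = self._tax(phyla)
        aaub = pd.Series([0.05] * 3 + [0.02] * 3, index=tax["genome_id"])
        fit = cb.fit_anova_aaub_phylum(aaub, tax)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.group_means["phylum"].tolist() == ["A", "B"]

    def test_ordered_means_recovered(self):
        rng = np.random.default_rng(3)
        phyla, values = [], []
        for j, mu in enumerate([0.02, 0.04, 0.06, 0.08]):
            phyla += [f"P{j}"] * 200
            values += list(rng.normal(mu, 0.005, 200))
        tax = self._tax(phyla)
        aaub = pd.Series(values, index=tax["genome_id"])
        fit = cb.fit_anova_aaub_phylum(aaub, tax)
        assert fit.group_means["phylum"].tolist() == ["P3", "P2", "P1", "P0"]
        assert fit.f_pvalue < 1e-6
        ranked = fit.ranked_means(min_size=20)
        assert len(ranked) == 4

    def test_size_threshold_filters_small_phyla(self):
        phyla = ["A"] * 25 + ["B"] * 5
        tax = self._tax(phyla)
        rng = np.random.default_rng(4)
        aaub = pd.Series(rng.uniform(0.01, 0.1, 30), index=tax["genome_id"])
        fit = cb.fit_anova_aaub_phylum(aaub, tax)
        assert fit.ranked_means(min_size=20)["phylum"].tolist() == ["A"]

    def test_single_phylum_degenerate(self):
        tax = self._tax(["A"] * 6)
        aaub = pd.Series(np.linspace(0.01, 0.06, 6), index=tax["genome_id"])
        with pytest.raises(DegenerateModelError):
            cb.fit_anova_aaub_phylum(aaub, tax)


class TestCompareAic:
    def test_identical_models_tie(self):
        data = simple_gam_data(seed=7)
        spec = cb.ModelSpec(response="y", smooth_terms=[("x", 10)])
        a = cb.fit_gam(spec, data)
        b = cb.fit_gam(spec, data)
        cmp_ = cb.compare_aic(a, b)
        assert cmp_.delta_aic == 0.0
        assert cmp_.preferred is None

    def test_pure_noise_parameter_penalised_on_average(self):
        deltas = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            data = simple_gam_data(seed=seed, n=150)
            data["junk"] = rng.standard_normal(len(data))
            base = cb.fit_gam(cb.ModelSpec(response="y", linear_terms=["x"],
                                           method="ML"), data)
            extra = cb.fit_gam(cb.ModelSpec(response="y", linear_terms=["x", "junk"],
                                            method="ML"), data)
            deltas.append(base.aic - extra.aic)
        assert np.mean(deltas) < 0  # simpler model preferred on average

    def test_strong_clustering_prefers_random_effects(self):
        wins = 0
        for seed in range(8):
            data, tax = grouped_regression_data(seed=100 + seed, m_groups=15,
                                                n_per=12, intercept_sd=0.8)
            spec_r = cb.ModelSpec(
                response="y", smooth_terms=[("x", 10)],
                random_structure=cb.RandomStructure(levels=("phylum",), slope_on="x"),
            )
            spec_f = cb.ModelSpec(response="y", smooth_terms=[("x", 10)])
            gamm = cb.fit_gamm(spec_r, data, tax)
            gam = cb.fit_gam(spec_f, data)
            cmp_ = cb.compare_aic(gamm, gam, "random", "fixed")
            wins += cmp_.preferred == "random" and -cmp_.delta_aic > 10
        assert wins >= 7

    def test_mismatched_observations_rejected(self):
        a = cb.fit_gam(cb.ModelSpec(response="y", linear_terms=["x"]),
                       simple_gam_data(seed=8))
        b = cb.fit_gam(cb.ModelSpec(response="y", linear_terms=["x"]),
                       simple_gam_data(seed=9))
        with pytest.raises(ContractViolation):
            cb.compare_aic(a, b)


class TestKlVsSize:
    def test_strong_size_association_detected(self):
        cohort = cb.simulate_cohort(
            cb.CohortConfig(n_phyla=15, genera_per_phylum=2, species_per_genus=2,
                            n_codons_per_genome=3000, seed=21)
        )
        from compbias.pipeline import profiles_to_frame

        profs, mets = cohort.profiles()
        df = profiles_to_frame(profs, mets).reset_index()
        # make size a strong deterministic function of KL
        rng = np.random.default_rng(0)
        df["genome_size"] = 1e6 * (1 + 5 * df["kl"]) + rng.normal(0, 1e3, len(df))
        fit = cb.fit_kl_vs_size(df, cohort.taxonomy)
        assert fit.fixed.loc["genome_size", "p"] < 1e-3
        assert fit.fixed.loc["genome_size", "estimate"] > 0

    def test_constant_size_degenerate(self):
        cohort = cb.simulate_cohort(
            cb.CohortConfig(n_phyla=4, genera_per_phylum=2, species_per_genus=2,
                            n_codons_per_genome=1000, seed=22)
        )
        from compbias.pipeline import profiles_to_frame

        profs, mets = cohort.profiles()
        df = profiles_to_frame(profs, mets).reset_index()
        df["genome_size"] = 1_000_000
        with pytest.raises(DegenerateModelError):
            cb.fit_kl_vs_size(df, cohort.taxonomy)
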