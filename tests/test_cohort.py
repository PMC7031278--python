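import itertools

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import networkx as nx

from csdbench.cohort import (CalibrationError, SemParameters, analysis_view,
                             bootstrap_resample, default_parameters,
                             population_covariance, simulate_cross_sectional,
                             simulate_longitudinal)
from csdbench.ges import fges_search
from csdbench.stats import partial_correlation

from conftest import to_networkx


class TestDefaultParameters:
    def test_age_marginal(self, params):
        assert params.marginals["AGE"] == (74.09, 7.46)

    def test_apoe4_mix(self, params):
        assert params.apoe4_probs == (0.54, 0.36, 0.10)

    def test_fdg_implied_marginal_closed_form(self, params):
        """Closed-form propagation puts the endogenous FDG marginal exactly
        at its calibration target."""
        cov = population_covariance(params)
        i = cov.index("FDG")
        assert cov.matrix[i, i] == pytest.approx(0.17**2, rel=1e-9)

    def test_noise_scales_positive(self, params):
        for design in ("cross_sectional", "longitudinal"):
            assert all(v > 0 for v in params.noise_scales(design).values())

    def test_child_r2_moderate(self, params):
        """Each endogenous child has R^2 in the moderate band."""
        from csdbench.cohort import _calibrate

        cal = _calibrate(params, "cross_sectional")
        for v, nv in cal.noise_var.items():
            if cal.parents[v]:
                assert 0.2 <= 1 - nv <= 0.6

    def test_infeasible_calibration_raises(self, params):
        coeffs = dict(params.coefficients)
        coeffs[("PTAU", "DX")] = 0.9
        coeffs[("FDG", "DX")] = -0.9
        bad = replace(params, coefficients=coeffs)
        with pytest.raises(CalibrationError):
            bad.noise_scales()

    def test_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        params.save(path)
        back = SemParameters.load(path)
        assert back.coefficients == params.coefficients
        assert back.dx_thresholds == pytest.approx(params.dx_thresholds)


class TestCrossSectional:
    def test_shape_and_columns(self, params):
        cohort = simulate_cross_sectional(params, 1008, seed=3)
        assert len(cohort) == 1008
        assert list(cohort.columns) == ["AGE", "SEX", "EDU", "APOE4", "ABETA",
                                        "PTAU", "FDG", "DX_star", "DX"]

    def test_empty_cohort_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_cross_sectional(params, 0, seed=1)

    def test_deterministic(self, params):
        a = simulate_cross_sectional(params, 50, seed=9)
        b = simulate_cross_sectional(params, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_no_missing_values(self, params):
        cohort = simulate_cross_sectional(params, 500, seed=2)
        assert not cohort.isna().any().any()

    def test_ols_recovers_generating_coefficients(self, params):
        """Least-squares oracle at n=100k: the regression of ABETA on its
        generating parents recovers the raw path coefficients within 3 SE."""
        n = 100_000
        cohort = simulate_cross_sectional(params, n, seed=17)
        X = np.column_stack([np.ones(n), cohort["AGE"], cohort["APOE4"]])
        y = cohort["ABETA"].to_numpy()
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        sd = {k: v[1] for k, v in params.marginals.items()}
        from csdbench.cohort import _exogenous_moments

        exo = _exogenous_moments(params)
        expect_age = params.coefficients[("AGE", "ABETA")] * sd["ABETA"] / sd["AGE"]
        expect_apoe = (params.coefficients[("APOE4", "ABETA")]
                       * sd["ABETA"] / exo["APOE4"][1])
        assert abs(beta[1] - expect_age) < 3 * se[1]
        assert abs(beta[2] - expect_apoe) < 3 * se[2]

    def test_marginal_calibration_large_sample(self, params):
        cohort = simulate_cross_sectional(params, 100_000, seed=23)
        for col in ("AGE", "EDU", "ABETA", "PTAU", "FDG"):
            mean, sd = params.marginals[col]
            se = sd / np.sqrt(len(cohort))
            assert abs(cohort[col].mean() - mean) < 4 * se
        dx = cohort["DX"].value_counts(normalize=True)
        for cls, target in enumerate((0.31, 0.46, 0.23)):
            assert abs(dx.get(float(cls), 0.0) - target) < 0.015

    def test_dsep_implied_partial_correlations_vanish(self, params):
        """Every d-separation of the generating DAG (|S| <= 2) shows up as
        a near-zero partial correlation at n=100k, on the latent scale."""
        from csdbench.gold import build_gold_standard
        from csdbench.stats import CovarianceModel

        cohort = simulate_cross_sectional(params, 100_000, seed=29)
        latent = cohort.drop(columns=["DX"]).rename(columns={"DX_star": "DX"})
        cov = CovarianceModel.from_dataframe(latent)
        g = to_networkx(build_gold_standard())
        nodes = sorted(g.nodes)
        checked = 0
        for x, y in itertools.combinations(nodes, 2):
            rest = [v for v in nodes if v not in (x, y)]
            for r in range(3):
                for s in itertools.combinations(rest, r):
                    if nx.is_d_separator(g, {x}, {y}, set(s)):
                        assert abs(partial_correlation(cov, x, y, s)) < 0.02
                        checked += 1
        assert checked > 20


class TestLongitudinal:
    def test_shape(self, params):
        cohort = simulate_longitudinal(params, 266, seed=4)
        assert len(cohort) == 266
        assert "ABETA.24" in cohort.columns and "AGE" in cohort.columns

    def test_zero_ar_decouples_visits(self, params):
        """With all AR weights zero the visit-24 block is independent of the
        visit-0 block given demographics (population computation)."""
        p0 = replace(params, ar_coefficients={v: 0.0 for v in
                                              params.ar_coefficients})
        cov = population_covariance(p0, "longitudinal")
        demo = ["AGE", "SEX", "EDU", "APOE4"]
        for v0 in ("ABETA.0", "PTAU.0", "FDG.0", "DX.0"):
            for v24 in ("ABETA.24", "PTAU.24", "FDG.24", "DX.24"):
                assert abs(partial_correlation(cov, v0, v24, demo)) < 1e-9

    def test_within_time_dependence_via_paths(self, params):
        """ABETA.24 -- PTAU.24 dependence given both visit-0 values exists
        through the within-time edge and vanishes when it is removed."""
        cov = population_covariance(params, "longitudinal")
        given = ["ABETA.0", "PTAU.0"]
        assert abs(partial_correlation(cov, "ABETA.24", "PTAU.24", given)) > 0.05
        coeffs = dict(params.coefficients)
        coeffs[("ABETA", "PTAU")] = 0.0
        p0 = replace(params, coefficients=coeffs)
        cov0 = population_covariance(p0, "longitudinal")
        assert abs(partial_correlation(cov0, "ABETA.24", "PTAU.24", given)) < 1e-9


class TestBootstrap:
    def test_single_row_identity(self, params):
        cohort = simulate_cross_sectional(params, 1, seed=5)
        pd.testing.assert_frame_equal(bootstrap_resample(cohort, seed=1), cohort)

    def test_deterministic(self, params):
        cohort = simulate_cross_sectional(params, 40, seed=6)
        a = bootstrap_resample(cohort, seed=11)
        b = bootstrap_resample(cohort, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_resample(pd.DataFrame({"A": []}), seed=1)

    def test_inclusion_frequency_binomial_oracle(self, params):
        """Each row appears in a resample with probability 1-(1-1/n)^n."""
        n, reps = 50, 2000
        cohort = simulate_cross_sectional(params, n, seed=7)
        cohort = cohort.assign(_row=np.arange(n))
        included = np.zeros(n)
        for b in range(reps):
            rs = bootstrap_resample(cohort, seed=b)
            included[np.unique(rs["_row"].to_numpy(dtype=int))] += 1
        expected = 1 - (1 - 1 / n) ** n
        # grand mean over rows and resamples; generous band for the
        # within-resample correlation between rows
        assert abs(included.mean() / reps - expected) < 0.01


def test_sign_flip_leaves_structure_invariant(params):
    """Flipping an effect sign changes correlations, not the recovered
    equivalence class (population covariance, so exact)."""
    cov = population_covariance(params, n=2000)
    g1 = fges_search(cov)
    coeffs = dict(params.coefficients)
    coeffs[("ABETA", "PTAU")] = -coeffs[("ABETA", "PTAU")]
    flipped = replace(params, coefficients=coeffs)
    g2 = fges_search(population_covariance(flipped, n=2000))
    assert g1 == g2


def test_analysis_view_drops_latent(params):
    cohort = simulate_longitudinal(params, 30, seed=8)
    view = analysis_view(cohort)
    assert not any(c.startswith("DX_star") for c in view.columns)
    assert "DX.0" in view.columns
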