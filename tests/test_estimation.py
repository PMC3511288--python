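"""Estimation: Halton draws, simulated likelihood, fitting, interactions."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, ndtri

import dcemix as dx
from dcemix.estimation import (
    MixedLogitSpec,
    _beta_draws,
    _build_draws,
    _make_transforms,
    _prepare,
    _radical_inverse,
    _triangular_ppf01,
    halton_draws,
    panel_simulated_loglik,
)
from dcemix.exceptions import (
    DataValidationError,
    IdentificationError,
    InvalidSpecificationError,
)
from dcemix.simulate import ChoiceDataset


def _toy_dataset(Xdiff, y, attr_names, covariates=None):
    """Build a ChoiceDataset from per-(respondent, task) difference rows."""
    rows = []
    for (r, t), xd, yy in zip(
        [(r, t) for r in range(1, Xdiff.shape[0] + 1) for t in range(Xdiff.shape[1])],
        Xdiff.reshape(-1, Xdiff.shape[2]),
        y.reshape(-1),
    ):
        for j, alt in enumerate("AB"):
            rows.append(
                {
                    "respondent": r,
                    "task": f"t{t}",
                    "alternative": alt,
                    "chosen": int(yy) if alt == "A" else 1 - int(yy),
                    **{a: (xd[k] if alt == "A" else 0.0) for k, a in enumerate(attr_names)},
                }
            )
    cov = covariates if covariates is not None else pd.DataFrame(
        index=pd.RangeIndex(1, Xdiff.shape[0] + 1, name="respondent")
    )
    return ChoiceDataset(pd.DataFrame(rows), cov)


class TestHalton:
    def test_base2_closed_form(self):
        u = halton_draws(1, 3, discard=0)[0, :, 0]
        assert np.allclose(u, [1 / 2, 1 / 4, 3 / 4])

    def test_base3_closed_form(self):
        u = halton_draws(2, 3, discard=0)[0, :, 1]
        assert np.allclose(u, [1 / 3, 2 / 3, 1 / 9])

    def test_low_discrepancy_vs_uniform(self):
        u = np.sort(halton_draws(1, 10_000, discard=0)[0, :, 0])
        grid = np.arange(1, 10_001) / 10_000
        sup = max(np.abs(u - grid).max(), np.abs(u - grid + 1 / 10_000).max())
        assert sup < 0.01

    def test_unsupported_dimension(self):
        with pytest.raises(InvalidSpecificationError):
            halton_draws(26, 10)

    def test_values_strictly_inside_unit_interval(self):
        u = halton_draws(5, 200, n_respondents=7, discard=10)
        assert u.shape == (7, 200, 5)
        assert (u > 0).all() and (u < 1).all()

    def test_respondents_get_distinct_subsequences(self):
        u = halton_draws(1, 50, n_respondents=3, discard=10)
        assert not np.allclose(u[0], u[1])
        # consecutive blocks of one global sequence
        pooled = _radical_inverse(np.arange(11, 11 + 150), 2)
        assert np.allclose(u.reshape(-1), pooled)

    def test_discard_drops_leading_points(self):
        full = halton_draws(1, 13, discard=0)[0, :, 0]
        dropped = halton_draws(1, 3, discard=10)[0, :, 0]
        assert np.allclose(dropped, full[10:])


class TestTriangularTransform:
    def test_inverse_cdf_endpoints_and_median(self):
        assert _triangular_ppf01(np.array([0.5]))[0] == pytest.approx(1.0)
        assert _triangular_ppf01(np.array([0.0]))[0] == pytest.approx(0.0)
        assert _triangular_ppf01(np.array([1.0]))[0] == pytest.approx(2.0)

    def test_sign_preservation_under_any_mean(self):
        """Every transformed cost draw keeps the sign of the cost mean."""
        spec = MixedLogitSpec(
            attributes=("cost",), mixing={"cost": "triangular"},
            include_asc=False, n_draws=64,
        )
        u = _build_draws(spec, 5)
        tf = _make_transforms(spec, u)
        for mean in (-3.0, -0.02, 0.015, 2.0):
            beta = _beta_draws(spec, tf, np.array([mean]), np.array([]), 5)
            assert (np.sign(beta) == np.sign(mean)).all()
            # spread is tied to the mean: support is [0, 2*mean]
            assert np.abs(beta).max() <= 2 * abs(mean)


class TestSimulatedLoglik:
    def test_single_task_identical_alternatives(self):
        Xd = np.zeros((1, 1, 1))
        y = np.array([[1.0]])
        data = _toy_dataset(Xd, y, ["a"])
        spec = MixedLogitSpec(attributes=("a",), include_asc=False, n_draws=1)
        ll = panel_simulated_loglik(spec, data, [0.7])
        assert ll == pytest.approx(math.log(0.5))

    def test_degenerate_mixing_equals_analytic_mnl(self, rng):
        n, T = 30, 4
        Xd = rng.normal(size=(n, T, 2))
        y = (rng.random((n, T)) < 0.5).astype(float)
        data = _toy_dataset(Xd, y, ["a", "b"])
        params = np.array([0.3, -0.8, 0.0, 0.0])  # sds zero
        spec = MixedLogitSpec(
            attributes=("a", "b"), mixing={"a": "normal", "b": "normal"},
            include_asc=False, n_draws=50,
        )
        ll = panel_simulated_loglik(spec, data, params)
        v = Xd @ params[:2]
        ll_analytic = np.sum(np.log(expit(np.where(y == 1, v, -v))))
        assert ll == pytest.approx(ll_analytic, abs=1e-10)

    def test_three_draw_brute_force_oracle(self):
        """2 respondents x 2 tasks, 1 normal coefficient, R=3: enumerate the
        draw average by hand with an independent radical-inverse routine."""
        Xd = np.array([[[1.0], [-2.0]], [[0.5], [3.0]]])
        y = np.array([[1.0, 0.0], [1.0, 1.0]])
        data = _toy_dataset(Xd, y, ["a"])
        m, s, discard = 0.4, 0.9, 10
        spec = MixedLogitSpec(
            attributes=("a",), mixing={"a": "normal"}, include_asc=False,
            n_draws=3, halton_discard=discard,
        )
        ll = panel_simulated_loglik(spec, data, [m, s])

        def rad_inv(i, base=2):
            out, f = 0.0, 1.0 / base
            while i:
                out += (i % base) * f
                i //= base
                f /= base
            return out

        expected = 0.0
        for i_resp in range(2):
            probs = []
            for r in range(3):
                u = rad_inv(discard + 1 + i_resp * 3 + r)
                beta = m + s * ndtri(u)
                p = 1.0
                for t in range(2):
                    v = Xd[i_resp, t, 0] * beta
                    p *= expit(v) if y[i_resp, t] == 1 else expit(-v)
                probs.append(p)
            expected += math.log(np.mean(probs))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_draw_count_stability(self, preset_data, preset, rng):
        """Simulated LL at fixed parameters approaches its high-draw limit;
        the simulation error shrinks with the draw count (averaged over a few
        parameter points, since convergence is not pointwise monotone)."""
        _, design = preset

        def spec_with(R):
            return MixedLogitSpec(
                attributes=tuple(design.factor_names),
                mixing={"side_effect_severity": "normal", "cost": "triangular"},
                n_draws=R,
            )

        base = np.zeros(spec_with(1).n_parameters())
        base[: len(spec_with(1).coefficient_names())] = [
            0.02, -0.16, -0.03, 0.01, 0.04, -0.02, -0.005, -0.0937, -0.01,
        ]
        base[-1] = 0.16
        points = [base * s for s in (0.5, 1.0, 1.5, 2.0)]
        grid = (50, 200, 1000)
        errs = {R: 0.0 for R in grid}
        for p in points:
            ref = panel_simulated_loglik(spec_with(4000), preset_data, p)
            for R in grid:
                errs[R] += abs(panel_simulated_loglik(spec_with(R), preset_data, p) - ref)
        assert errs[50] > errs[200] > errs[1000]


class TestFit:
    def test_conditional_logit_matches_statsmodels(self, clogit_result, clogit_spec, preset_data):
        """With no mixing the MSL fit is a plain conditional logit; an
        independent textbook implementation must agree to 4 decimals."""
        prep = _prepare(clogit_spec, preset_data)
        Xf = prep.Xd.reshape(-1, prep.Xd.shape[2])
        yf = prep.y.reshape(-1)
        oracle = sm.Logit(yf, Xf).fit(disp=0)
        assert np.abs(clogit_result.params - oracle.params).max() < 1e-4
        assert clogit_result.loglik == pytest.approx(oracle.llf, abs=1e-6)
        se = np.sqrt(np.diag(clogit_result.cov))
        assert np.abs(se - oracle.bse).max() < 1e-4

    def test_identification_error_names_attribute(self, rng):
        n, T = 10, 3
        Xd = rng.normal(size=(n, T, 2))
        Xd[:, :, 1] = 0.0  # 'b' never differs between alternatives
        y = (rng.random((n, T)) < 0.5).astype(float)
        data = _toy_dataset(Xd, y, ["a", "b"])
        spec = MixedLogitSpec(attributes=("a", "b"), include_asc=False, n_draws=1)
        with pytest.raises(IdentificationError, match="b"):
            dx.fit(spec, data)

    def test_refit_from_optimum_is_a_fixed_point(self, clogit_spec, preset_data, clogit_result):
        refit = dx.fit(clogit_spec, preset_data, start=clogit_result.params)
        assert refit.n_iter <= 2
        assert refit.loglik == pytest.approx(clogit_result.loglik, abs=1e-6)

    def test_fixed_coefficient_recovery(self, preset, rng):
        """Known fixed coefficients are recovered within 3 SE at large n."""
        _, design = preset
        truth = {
            "side_effect_severity": -0.16, "future_side_effect_risk": -0.03,
            "symptom_reduction": 0.01, "death_risk_reduction": 0.04,
            "cost": -0.02, "symptom_severity": -0.005, "regimen": -0.0937,
            "alcohol_restriction": -0.01,
        }
        n = 800
        coeffs = pd.DataFrame(
            {k: [v] * n for k, v in truth.items()},
            index=pd.RangeIndex(1, n + 1, name="respondent"),
        )
        data = dx.simulate_choices(design, coeffs, seed=17)
        spec = MixedLogitSpec(attributes=tuple(design.factor_names), n_draws=1)
        result = dx.fit(spec, data)
        se = np.sqrt(np.diag(result.cov))
        names = result.spec.coefficient_names()
        for i, name in enumerate(names):
            target = 0.0 if name == "asc" else truth[name]
            assert abs(result.params[i] - target) <= 3 * se[i], name

    def test_permutation_invariance(self, clogit_spec, preset_data, clogit_result, rng):
        shuffled_rows = preset_data.choices.sample(frac=1.0, random_state=5)
        data2 = ChoiceDataset(shuffled_rows, preset_data.covariates)
        r2 = dx.fit(clogit_spec, data2)
        assert np.allclose(r2.params, clogit_result.params, atol=1e-8)
        assert r2.loglik == pytest.approx(clogit_result.loglik, abs=1e-8)

    def test_determinism(self, mixed_spec, preset_data, mixed_result):
        again = dx.fit(mixed_spec, preset_data)
        assert np.array_equal(again.params, mixed_result.params)
        assert again.loglik == mixed_result.loglik

    def test_nonconvergence_is_flagged(self, clogit_spec, preset_data):
        result = dx.fit(clogit_spec, preset_data, maxiter=1)
        assert not result.converged


class TestInteractions:
    def test_interaction_column_all_zero_unidentified(self, preset, preset_data):
        _, design = preset
        cov = preset_data.covariates.copy()
        cov["phi"] = 0
        data = ChoiceDataset(preset_data.choices, cov)
        spec = MixedLogitSpec(
            attributes=tuple(design.factor_names),
            interactions=(("cost", "phi"),), n_draws=1,
        )
        with pytest.raises(IdentificationError, match="cost:phi"):
            dx.fit(spec, data)

    def test_reparameterization_invariance(self, preset, preset_data):
        """cost + cost x PHI spans the same model as two group-specific cost
        columns; the optimal log-likelihood must coincide."""
        _, design = preset
        spec_int = MixedLogitSpec(
            attributes=tuple(design.factor_names),
            interactions=(("cost", "phi"),), n_draws=1,
        )
        r_int = dx.fit(spec_int, preset_data)

        df = preset_data.choices.copy()
        phi = preset_data.covariates["phi"].reindex(df["respondent"]).to_numpy()
        df["cost_phi0"] = df["cost"].to_numpy() * (1 - phi)
        df["cost_phi1"] = df["cost"].to_numpy() * phi
        attrs = [a for a in design.factor_names if a != "cost"] + ["cost_phi0", "cost_phi1"]
        data2 = ChoiceDataset(df, preset_data.covariates)
        r_grp = dx.fit(MixedLogitSpec(attributes=tuple(attrs), n_draws=1), data2)
        assert r_grp.loglik == pytest.approx(r_int.loglik, abs=1e-6)
        # and the reparameterization maps back: cost_phi1 = cost + interaction
        m = r_int.means
        assert r_grp.means["cost_phi0"] == pytest.approx(m["cost"], abs=1e-5)
        assert r_grp.means["cost_phi1"] == pytest.approx(
            m["cost"] + m["cost:phi"], abs=1e-5
        )

    def test_interaction_recovery(self, preset):
        """A +0.004 cost-sensitivity deviation for insured respondents is
        recovered with the right sign and within 3 SE."""
        _, design = preset
        n = 1200
        rng = np.random.default_rng(99)
        phi = (rng.random(n) < 0.5).astype(int)
        cov = pd.DataFrame({"phi": phi}, index=pd.RangeIndex(1, n + 1, name="respondent"))
        base = {
            "side_effect_severity": -0.16, "future_side_effect_risk": -0.03,
            "symptom_reduction": 0.01, "death_risk_reduction": 0.04,
            "cost": -0.020, "symptom_severity": -0.005, "regimen": -0.0937,
            "alcohol_restriction": -0.01,
        }
        coeffs = pd.DataFrame(
            {k: [v] * n for k, v in base.items()},
            index=pd.RangeIndex(1, n + 1, name="respondent"),
        )
        data = dx.simulate_choices(
            design, coeffs, covariates=cov,
            interactions=[("cost", "phi", 0.004)], seed=23,
        )
        spec = MixedLogitSpec(
            attributes=tuple(design.factor_names),
            interactions=(("cost", "phi"),), n_draws=1,
        )
        result = dx.fit(spec, data)
        idx = result.spec.param_names().index("mean:cost:phi")
        est, se = result.params[idx], np.sqrt(result.cov[idx, idx])
        assert est > 0
        assert abs(est - 0.004) <= 3 * se

    def test_add_interactions_matches_spec_route(self, preset, preset_data):
        _, design = preset
        spec = MixedLogitSpec(attributes=tuple(design.factor_names), n_draws=1)
        sp2, data2 = dx.add_interactions(spec, preset_data, [("cost", "phi")])
        ll_materialized = dx.fit(sp2, data2).loglik
        sp3 = MixedLogitSpec(
            attributes=tuple(design.factor_names),
            interactions=(("cost", "phi"),), n_draws=1,
        )
        ll_spec = dx.fit(sp3, preset_data).loglik
        assert ll_materialized == pytest.approx(ll_spec, abs=1e-8)

    def test_missing_covariate_is_explicit_error(self, preset, preset_data):
        _, design = preset
        cov = preset_data.covariates.copy()
        cov.loc[cov.index[0], "phi"] = np.nan
        data = ChoiceDataset(preset_data.choices, cov)
        spec = MixedLogitSpec(
            attributes=tuple(design.factor_names),
            interactions=(("cost", "phi"),), n_draws=1,
        )
        with pytest.raises(DataValidationError, match="phi"):
            dx.fit(spec, data)


class TestStepwise:
    def _data_with_noise_covariate(self, preset):
        pop, design = preset
        data = dx.simulate_dataset(pop, design, seed=77)
        rng = np.random.default_rng(7)
        cov = data.covariates.copy()
        cov["noise"] = rng.integers(0, 2, size=len(cov))
        return dx.ChoiceDataset(data.choices, cov), design

    def test_alpha_in_zero_adds_nothing(self, preset):
        data, design = self._data_with_noise_covariate(preset)
        base = MixedLogitSpec(attributes=tuple(design.factor_names), n_draws=1)
        trace, final, _ = dx.stepwise_covariates(
            base, data, [("cost", "phi"), ("cost", "noise")], alpha_in=0.0
        )
        assert final.interactions == ()
        assert all(t["step"] != "add" for t in trace)

    def test_true_interaction_selected_noise_rejected(self, preset):
        """With a strong simulated cost x group effect, forward selection
        picks the real covariate and leaves the pure-noise one out."""
        _, design = preset
        n = 1000
        rng = np.random.default_rng(13)
        grp = (rng.random(n) < 0.5).astype(int)
        cov = pd.DataFrame(
            {"grp": grp, "noise": rng.integers(0, 2, size=n)},
            index=pd.RangeIndex(1, n + 1, name="respondent"),
        )
        base_means = {
            "side_effect_severity": -0.16, "future_side_effect_risk": -0.03,
            "symptom_reduction": 0.01, "death_risk_reduction": 0.04,
            "cost": -0.030, "symptom_severity": -0.005, "regimen": -0.0937,
            "alcohol_restriction": -0.01,
        }
        coeffs = pd.DataFrame(
            {k: [v] * n for k, v in base_means.items()},
            index=pd.RangeIndex(1, n + 1, name="respondent"),
        )
        data = dx.simulate_choices(
            design, coeffs, covariates=cov,
            interactions=[("cost", "grp", 0.02)], seed=29,
        )
        base = MixedLogitSpec(attributes=tuple(design.factor_names), n_draws=1)
        trace, final, result = dx.stepwise_covariates(
            base, data, [("cost", "grp"), ("cost", "noise")]
        )
        assert ("cost", "grp") in final.interactions
        assert ("cost", "noise") not in final.interactions
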