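import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from follisig import hurdle, simulate
from follisig.core import MT, STAGES, InvalidArgument
from follisig.hurdle import CELL_LABELS, _Structure


def _mini_panel(design, seed=0, **kwargs):
    params = simulate.HurdleSimParams(n_genes=kwargs.pop("n_genes", 10), seed=seed, **kwargs)
    return simulate.simulate_hurdle_panel(design, params), params


class TestAugmentation:
    def test_partially_detected_cell_not_padded(self, design, small_panel):
        panel, _ = small_panel
        aug = hurdle.augment_null_expression(panel.rel, panel.det, design)
        # for every augmented record the source cell has zero detections
        lcm = design[design["compartment"] != MT]
        for _, row in aug[aug["augmented"]].iterrows():
            cols = lcm.loc[
                (lcm["stage"] == row["stage"]) & (lcm["compartment"] == row["compartment"]),
                "sample_id",
            ]
            assert panel.det.loc[row["gene"], cols].sum() == 0
            assert row["y"] == 0.0

    def test_exactly_one_zero_per_silent_cell(self, design):
        det = pd.DataFrame(0, index=["g1"], columns=design[design.compartment != MT]["sample_id"])
        rel = det.replace(0, np.nan).astype(float)
        aug = hurdle.augment_null_expression(rel, det, design)
        assert len(aug) == 8  # one zero record per stage x compartment cell
        assert aug["augmented"].all()

    def test_fully_detected_panel_unchanged(self, design):
        cols = design[design.compartment != MT]["sample_id"]
        det = pd.DataFrame(1, index=["g1", "g2"], columns=cols)
        rel = pd.DataFrame(np.full((2, len(cols)), 5.0), index=["g1", "g2"], columns=cols)
        aug = hurdle.augment_null_expression(rel, det, design)
        assert not aug["augmented"].any()
        assert len(aug) == 2 * len(cols)


class TestLevelModel:
    def test_constant_levels_reduce_to_constant_fit(self, design):
        cols = design[design.compartment != MT]["sample_id"]
        det = pd.DataFrame(1, index=["g1", "g2", "g3"], columns=cols)
        rel = pd.DataFrame(16.0, index=det.index, columns=cols)
        fit = hurdle.fit_level_model(hurdle.augment_null_expression(rel, det, design))
        np.testing.assert_allclose(fit.beta, 2.0, atol=1e-6)  # 16 ** 0.25
        assert fit.resid_sd < 1e-4
        assert np.abs(fit.modes.to_numpy()).max() < 1e-4

    def test_scaling_equivariance(self, design, small_panel):
        panel, _ = small_panel
        fit1 = hurdle.fit_level_model(hurdle.augment_null_expression(panel.rel, panel.det, design))
        fit16 = hurdle.fit_level_model(
            hurdle.augment_null_expression(panel.rel * 16.0, panel.det, design)
        )
        np.testing.assert_allclose(fit16.beta, 2.0 * fit1.beta, rtol=1e-4)
        np.testing.assert_allclose(fit16.cov, 4.0 * fit1.cov, rtol=1e-2, atol=5e-3)
        assert fit16.resid_sd == pytest.approx(2.0 * fit1.resid_sd, rel=1e-4)

    def test_loglik_is_monotone(self, design, fitted_panel):
        _, _, fit = fitted_panel
        diffs = np.diff(fit.level.loglik_trace)
        assert (diffs >= -1e-7).all()

    def test_too_few_observations_rejected(self, design):
        aug = pd.DataFrame(
            {"gene": ["g1"] * 3, "sample_id": [""] * 3, "stage": ["PD"] * 3,
             "compartment": ["O"] * 3, "y": [1.0] * 3, "augmented": [False] * 3}
        )
        with pytest.raises(InvalidArgument):
            hurdle.fit_level_model(aug)


class TestPresenceModel:
    def test_all_detected_engages_ridge_and_flags_separation(self, design):
        cols = design[design.compartment != MT]["sample_id"]
        det = pd.DataFrame(1, index=["g1", "g2", "g3"], columns=cols)
        fit = hurdle.fit_presence_model(det, design)
        assert fit.separation
        assert fit.ridge_used > 0
        assert (fit.beta > 2).all()  # pushed toward the penalty ceiling

    def test_balanced_unstructured_detection_gives_null_logits(self, design):
        rng = np.random.default_rng(0)
        cols = design[design.compartment != MT]["sample_id"]
        det = pd.DataFrame(
            rng.integers(0, 2, (40, len(cols))), index=[f"g{i}" for i in range(40)], columns=cols
        )
        fit = hurdle.fit_presence_model(det, design)
        assert (fit.beta.abs() <= 3 * fit.beta_se + 1e-8).all()

    def test_laplace_objective_monotone(self, design, fitted_panel):
        _, _, fit = fitted_panel
        diffs = np.diff(fit.presence.loglik_trace)
        assert (diffs >= -1e-6).all()

    def test_needs_two_stages_and_two_genes(self, design):
        cols = design[design.compartment != MT]["sample_id"]
        det = pd.DataFrame(1, index=["g1"], columns=cols)
        with pytest.raises(InvalidArgument):
            hurdle.fit_presence_model(det, design)


class TestLaplaceAgainstQuadrature:
    def test_small_instance_matches_adaptive_quadrature(self):
        # 2 genes x 2 stages x 2 replicates, stage-only effects with a small
        # fixed covariance: the Laplace error is far below the tolerance, so
        # this checks the Laplace evaluation itself
        rows = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "compartment": ["O"] * 4,
                "stage": ["PD", "PD", "PM", "PM"],
                "replicate": [1, 2, 1, 2],
            }
        )
        det = pd.DataFrame([[1, 0, 1, 1], [0, 0, 1, 0]], index=["g1", "g2"], columns=rows["sample_id"])
        st_obj = _Structure("stage_only")
        s_idx = np.array([0, 0, 1, 1])
        c_idx = np.array([0, 0, 0, 0])
        x = np.zeros((4, 8))
        x[np.arange(4), c_idx * 4 + s_idx] = 1.0
        z_design = st_obj.z_matrix(s_idx, c_idx)
        beta = np.array([0.3, -0.2, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        sigma2 = 0.002
        g_cov = sigma2 * np.eye(4)
        z_mat = det.to_numpy(dtype=float)

        # conditional modes found independently with a generic optimizer
        def neg_pen(v_flat):
            v = v_flat.reshape(2, 4)
            eta = x @ beta + (z_design @ v.T).T
            ll = np.sum(z_mat * eta - np.logaddexp(0, eta))
            return -(ll - 0.5 * np.sum(v**2) / sigma2)

        res = optimize.minimize(neg_pen, np.zeros(8), method="BFGS", options={"gtol": 1e-12})
        v_hat = res.x.reshape(2, 4)
        lap = hurdle.laplace_marginal_loglik(z_mat, x, z_design, beta, v_hat, g_cov)

        # independent 2D adaptive quadrature per gene (the two unused stage
        # dimensions integrate to one exactly)
        total = 0.0
        for gi in range(2):
            zg = z_mat[gi]

            def integrand(b_pm, b_pd):
                eta = x @ beta + z_design[:, 0] * b_pd + z_design[:, 1] * b_pm
                lik = np.exp(np.sum(zg * eta - np.logaddexp(0, eta)))
                dens = stats.norm.pdf(b_pd, scale=np.sqrt(sigma2)) * stats.norm.pdf(
                    b_pm, scale=np.sqrt(sigma2)
                )
                return lik * dens

            lim = 6 * np.sqrt(sigma2)
            val, err = integrate.dblquad(integrand, -lim, lim, -lim, lim, epsabs=1e-13, epsrel=1e-12)
            total += np.log(val)
        assert lap == pytest.approx(total, abs=1e-6)


class TestHurdleBundle:
    def test_zero_covariance_truth_reduces_to_cell_summaries(self, design):
        p = simulate.HurdleSimParams(
            n_genes=30,
            stage_cov_binary=np.zeros((4, 4)),
            stage_cov_level=np.zeros((4, 4)),
            cell_cov_binary=np.zeros((2, 2)),
            cell_cov_level=np.zeros((2, 2)),
            resid_sd=0.3,
            seed=21,
        )
        panel = simulate.simulate_hurdle_panel(design, p)
        fit = hurdle.fit_hurdle(panel.det, panel.rel, design)
        lcm = design[design["compartment"] != MT]
        for ci, comp in enumerate(("O", "GC")):
            for si, stage in enumerate(STAGES):
                cols = lcm.loc[(lcm.stage == stage) & (lcm.compartment == comp), "sample_id"]
                emp_rate = panel.det[cols].to_numpy().mean()
                est_p = 1 / (1 + np.exp(-fit.presence.beta[f"{stage}:{comp}"]))
                assert est_p == pytest.approx(emp_rate, abs=0.1)
                # closed-form target includes the augmented null records
                aug = hurdle.augment_null_expression(panel.rel, panel.det, design)
                cell = aug[(aug["stage"] == stage) & (aug["compartment"] == comp)]
                target = (cell["y"] ** 0.25).mean()
                assert fit.level.beta[f"{stage}:{comp}"] == pytest.approx(target, abs=0.1)

    def test_empty_gene_intersection_rejected(self, design, small_panel):
        panel, _ = small_panel
        det = panel.det.rename(index=lambda g: g + "_other")
        with pytest.raises(InvalidArgument):
            hurdle.fit_hurdle(det, panel.rel, design)

    def test_refit_is_deterministic(self, design, small_panel):
        panel, _ = small_panel
        f1 = hurdle.fit_hurdle(panel.det, panel.rel, design)
        f2 = hurdle.fit_hurdle(panel.det, panel.rel, design)
        pd.testing.assert_series_equal(f1.presence.beta, f2.presence.beta)
        pd.testing.assert_series_equal(f1.level.beta, f2.level.beta)
        pd.testing.assert_frame_equal(f1.presence.modes, f2.presence.modes)
        assert f1.level.resid_sd == f2.level.resid_sd


class TestCorrelationReport:
    def _part(self, cov, part="presence"):
        labels = list(STAGES) + ["O", "GC"]
        full = np.zeros((6, 6))
        full[:4, :4] = cov
        full[4:, 4:] = np.eye(2)
        return hurdle.PartFit(
            part=part,
            structure="stage_plus_cell",
            beta=pd.Series(0.0, index=CELL_LABELS),
            beta_se=pd.Series(1.0, index=CELL_LABELS),
            cov=pd.DataFrame(full, index=labels, columns=labels),
            modes=pd.DataFrame(np.zeros((3, 6)), index=list("abc"), columns=labels),
            mode_cov=np.zeros((3, 6, 6)),
            loglik=0.0,
        )

    def test_diagonal_covariance_gives_zero_correlations(self):
        fit = hurdle.HurdleFit(self._part(np.diag([1, 2, 3, 4.0])), self._part(np.eye(4), "level"), list("abc"))
        rep = hurdle.stage_effect_correlations(fit)
        overall = rep["presence"]["overall"].to_numpy()
        assert np.allclose(overall - np.eye(4), 0.0)

    def test_rank_one_covariance_gives_unit_correlations(self):
        fit = hurdle.HurdleFit(self._part(np.ones((4, 4))), self._part(np.eye(4), "level"), list("abc"))
        rep = hurdle.stage_effect_correlations(fit)
        assert np.allclose(rep["presence"]["overall"].to_numpy(), 1.0)

    def test_zero_variance_reported_as_undefined(self):
        cov = np.diag([1.0, 0.0, 1.0, 1.0])
        fit = hurdle.HurdleFit(self._part(cov), self._part(np.eye(4), "level"), list("abc"))
        rep = hurdle.stage_effect_correlations(fit)
        overall = rep["presence"]["overall"]
        assert np.isnan(overall.loc["PM", "PM"]) or np.isnan(overall.loc["PD", "PM"])

    def test_recovers_negative_pd_sa_structure(self, design, fitted_panel):
        _, params, fit = fitted_panel
        rep = hurdle.stage_effect_correlations(fit)
        assert rep["level"]["overall"].loc["PD", "SA"] < -0.5
        assert rep["presence"]["overall"].loc["PD", "PM"] > 0.7
        # within-compartment report exists for both compartments
        assert set(rep["level"]["within"]) == {"O", "GC"}


class TestComponentSignificance:
    def test_strong_stage_structure_is_significant(self, design, fitted_panel):
        panel, _, _ = fitted_panel
        sig = hurdle.random_effect_significance(panel.det, None, design, part="presence")
        stage_p = sig.set_index("component").loc["stage", "pval"]
        assert stage_p < 1e-4
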