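import numpy as np
import pandas as pd
import pytest

from follisig import hurdle, predict, simulate
from follisig.core import COMPARTMENTS, STAGES, InvalidArgument
from follisig.hurdle import CELL_LABELS


def _toy_fit(p_grid, mu_grid, genes, resid_sd=0.5):
    """HurdleFit with explicit per-gene detection probabilities and level
    means: p_grid/mu_grid map gene -> (4 stages x 2 compartments) arrays."""
    labels = list(STAGES) + list(COMPARTMENTS)

    def part(part_name, cell_grids, transform):
        # put everything into per-gene unstructured cell modes, zero beta
        modes = []
        for g in genes:
            grid = transform(np.asarray(cell_grids[g], dtype=float))
            modes.append(grid.T.ravel())  # cell order = CELL_LABELS
        return hurdle.PartFit(
            part=part_name,
            structure="unstructured",
            beta=pd.Series(0.0, index=CELL_LABELS),
            beta_se=pd.Series(1.0, index=CELL_LABELS),
            cov=pd.DataFrame(np.eye(8), index=CELL_LABELS, columns=CELL_LABELS),
            modes=pd.DataFrame(modes, index=genes, columns=CELL_LABELS),
            mode_cov=np.zeros((len(genes), 8, 8)),
            loglik=0.0,
            resid_sd=resid_sd if part_name == "level" else None,
        )

    logit = lambda p: np.log(p / (1 - p))
    return hurdle.HurdleFit(
        presence=part("presence", p_grid, logit),
        level=part("level", mu_grid, lambda m: m),
        genes=list(genes),
    )


def _obs(comp, z, y, genes):
    return predict.ObservationVector(
        compartment=comp,
        z=pd.Series(z, index=genes),
        y=pd.Series(y, index=genes, dtype=float),
    )


def _brute_force_posterior(fit, obs, prior=None, include_level=True):
    """Plain-product Bayes enumeration, no log-space arithmetic."""
    from scipy.stats import norm

    prior = np.full(4, 0.25) if prior is None else np.asarray(prior, float)
    prior = prior / prior.sum()
    ci = COMPARTMENTS.index(obs.compartment)
    lik = np.ones(4)
    for s in range(4):
        for gene in obs.z.index:
            p = fit.detection_prob(gene)[s, ci]
            z = obs.z[gene]
            lik[s] *= p if z == 1 else (1 - p)
            if include_level and z == 1:
                mu = fit.level_mean(gene)[s, ci]
                lik[s] *= norm.pdf(obs.y[gene] ** 0.25, mu, fit.resid_sd)
    post = prior * lik
    return post / post.sum()


class TestPosteriorStage:
    def test_identical_stages_give_uniform_posterior(self):
        genes = ["g1", "g2"]
        p = {g: np.full((4, 2), 0.7) for g in genes}
        mu = {g: np.full((4, 2), 2.0) for g in genes}
        fit = _toy_fit(p, mu, genes)
        post = predict.posterior_stage(fit, _obs("O", [1, 0], [16.0, np.nan], genes))
        np.testing.assert_allclose(post.probs, 0.25, atol=1e-12)

    def test_two_stage_level_example(self):
        # one gene always detected; fourth-root means 1 (PD) vs 3 (PM),
        # resid 0.5, observed y^(1/4) = 1, prior mass on PD and PM only:
        # log LR = (2^2 - 0^2) / (2 * 0.25) = 8
        genes = ["g"]
        p = {"g": np.full((4, 2), 1 - 1e-12)}
        mu = {"g": np.array([[1.0, 1.0], [3.0, 3.0], [50.0, 50.0], [50.0, 50.0]])}
        fit = _toy_fit(p, mu, genes, resid_sd=0.5)
        post = predict.posterior_stage(
            fit, _obs("O", [1], [1.0], genes), prior=[0.5, 0.5, 0.0, 0.0]
        )
        assert post.probs["PD"] == pytest.approx(1 / (1 + np.exp(-8)), rel=1e-9)

    def test_prior_odds_scale_posterior_odds(self, fitted_panel):
        panel, _, fit = fitted_panel
        obs = _obs_from_panel(panel, "PD", "O")
        a = predict.posterior_stage(fit, obs, prior=[0.25, 0.25, 0.25, 0.25])
        b = predict.posterior_stage(fit, obs, prior=[0.4, 0.2, 0.2, 0.2])
        odds_a = a.probs["PD"] / a.probs["PM"]
        odds_b = b.probs["PD"] / b.probs["PM"]
        assert odds_b == pytest.approx(2 * odds_a, rel=1e-9)

    def test_matches_brute_force_enumeration(self, rng):
        genes = ["g1", "g2", "g3"]
        for trial in range(25):
            p = {g: rng.uniform(0.05, 0.95, (4, 2)) for g in genes}
            mu = {g: rng.uniform(0.5, 3.5, (4, 2)) for g in genes}
            fit = _toy_fit(p, mu, genes, resid_sd=0.6)
            z = rng.integers(0, 2, 3)
            y = np.where(z == 1, rng.uniform(0.5, 30.0, 3), np.nan)
            comp = "O" if trial % 2 else "GC"
            obs = _obs(comp, z, y, genes)
            prior = rng.dirichlet(np.ones(4))
            full = predict.posterior_stage(fit, obs, prior=prior)
            np.testing.assert_allclose(
                full.probs, _brute_force_posterior(fit, obs, prior), atol=1e-10
            )
            binary = predict.posterior_stage_binary_only(fit, obs, prior=prior)
            np.testing.assert_allclose(
                binary.probs,
                _brute_force_posterior(fit, obs, prior, include_level=False),
                atol=1e-10,
            )

    def test_gene_permutation_invariance(self, fitted_panel):
        panel, _, fit = fitted_panel
        obs = _obs_from_panel(panel, "SC", "GC")
        perm = predict.ObservationVector(
            compartment=obs.compartment, z=obs.z.iloc[::-1], y=obs.y.iloc[::-1]
        )
        a = predict.posterior_stage(fit, obs)
        b = predict.posterior_stage(fit, perm)
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)

    def test_uninformative_gene_leaves_posterior_unchanged(self, rng):
        genes = ["g1", "g2"]
        p = {g: rng.uniform(0.2, 0.8, (4, 2)) for g in genes}
        mu = {g: rng.uniform(1, 3, (4, 2)) for g in genes}
        fit2 = _toy_fit(p, mu, genes)
        genes3 = genes + ["flat"]
        p["flat"] = np.full((4, 2), 0.6)
        mu["flat"] = np.full((4, 2), 2.0)
        fit3 = _toy_fit(p, mu, genes3)
        a = predict.posterior_stage(fit2, _obs("O", [1, 0], [5.0, np.nan], genes))
        b = predict.posterior_stage(fit3, _obs("O", [1, 0, 1], [5.0, np.nan, 16.0], genes3))
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)


class TestBinaryOnly:
    def test_level_information_discarded(self):
        genes = ["g"]
        p = {"g": np.full((4, 2), 0.5)}
        mu = {"g": np.array([[1.0, 1], [2, 2], [3, 3], [4, 4]])}
        fit = _toy_fit(p, mu, genes)
        post = predict.posterior_stage_binary_only(fit, _obs("O", [1], [16.0], genes))
        np.testing.assert_allclose(post.probs, 0.25, atol=1e-12)

    def test_two_stage_bernoulli_example(self):
        genes = ["g"]
        grid = np.full((4, 2), 1e-9)
        grid[0, :] = 0.9
        grid[1, :] = 0.1
        fit = _toy_fit({"g": grid}, {"g": np.full((4, 2), 2.0)}, genes)
        post = predict.posterior_stage_binary_only(
            fit, _obs("O", [1], [16.0], genes), prior=[0.5, 0.5, 0, 0]
        )
        assert post.probs["PD"] == pytest.approx(0.9, rel=1e-6)

    def test_huge_residual_sd_makes_full_model_binary(self, fitted_panel):
        panel, _, fit = fitted_panel
        flat = hurdle.HurdleFit(
            presence=fit.presence,
            level=hurdle.PartFit(**{**fit.level.__dict__, "resid_sd": 1e9}),
            genes=fit.genes,
        )
        obs = _obs_from_panel(panel, "PM", "O")
        a = predict.posterior_stage(flat, obs)
        b = predict.posterior_stage_binary_only(flat, obs)
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-6)


def _obs_from_panel(panel, stage, comp):
    col = f"{stage}{'O' if comp == 'O' else 'G'}_1"
    z = panel.det[col]
    y = panel.rel[col].where(z == 1)
    return predict.ObservationVector(compartment=comp, z=z, y=y)


class TestResampling:
    def test_single_replicate_cell_gives_identical_vectors(self, design, small_panel):
        panel, _ = small_panel
        one = design[(design.stage != "PD") | (design.compartment != "O")].copy()
        keep = one[~((one.stage == "PM") & (one.compartment == "O") & (one.replicate > 1))]
        vecs = predict.resample_vectors(panel.rel, panel.det, keep, "PM", "O", n=5, seed=1)
        for v in vecs[1:]:
            pd.testing.assert_series_equal(v.z, vecs[0].z)
            pd.testing.assert_series_equal(v.y, vecs[0].y)

    def test_seeded_rerun_reproduces_vectors(self, design, small_panel):
        panel, _ = small_panel
        a = predict.resample_vectors(panel.rel, panel.det, design, "SC", "GC", n=10, seed=3)
        b = predict.resample_vectors(panel.rel, panel.det, design, "SC", "GC", n=10, seed=3)
        for va, vb in zip(a, b):
            pd.testing.assert_series_equal(va.z, vb.z)

    def test_replicates_drawn_uniformly(self, design, small_panel):
        panel, _ = small_panel
        rel = panel.rel.copy()
        det = panel.det.copy()
        # make every replicate value distinct and detected so the source is
        # identifiable
        cols = design[(design.stage == "SA") & (design.compartment == "GC")]["sample_id"]
        for k, c in enumerate(cols):
            det[c] = 1
            rel[c] = float(k + 1)
        n = 4000
        vecs = predict.resample_vectors(rel, det, design, "SA", "GC", n=n, seed=9)
        draws = np.array([v.y.iloc[0] for v in vecs])
        freqs = np.array([(draws == k + 1).mean() for k in range(len(cols))])
        tol = 3 * np.sqrt(0.25 * 0.75 / n)
        np.testing.assert_allclose(freqs, 0.25, atol=tol)

    def test_z_y_pairs_travel_together(self, design, small_panel):
        panel, _ = small_panel
        vecs = predict.resample_vectors(panel.rel, panel.det, design, "PD", "O", n=50, seed=4)
        for v in vecs:
            assert v.y[v.z == 0].isna().all()
            assert v.y[v.z == 1].notna().all()

    def test_empty_cell_fails(self, design, small_panel):
        panel, _ = small_panel
        no_pd = design[design.stage != "PD"]
        with pytest.raises(InvalidArgument):
            predict.resample_vectors(panel.rel, panel.det, no_pd, "PD", "O", n=5, seed=0)


class TestInformativeness:
    def test_full_model_never_less_informative_than_binary(self, design):
        """Adding the level term can only sharpen the posterior on average:
        mean posterior of the true stage under the full model stays within
        0.02 of or above the binary-only variant on matched panels."""
        for seed in range(20):
            params = simulate.HurdleSimParams.separated_panel(seed=seed)
            panel = simulate.simulate_hurdle_panel(design, params)
            fit = hurdle.fit_hurdle(panel.det, panel.rel, design)
            rng = np.random.default_rng(seed)
            vectors = {
                (s, c): predict.resample_vectors(panel.rel, panel.det, design, s, c, n=10, seed=rng)
                for c in COMPARTMENTS
                for s in STAGES
            }
            full = predict.evaluate_predictions(fit, vectors, "full")
            binary = predict.evaluate_predictions(fit, vectors, "binary")
            assert (
                full.mean_true_posterior.to_numpy().mean()
                >= binary.mean_true_posterior.to_numpy().mean() - 0.02
            )


class TestEvaluatePredictions:
    def test_empty_input_gives_empty_report(self, fitted_panel):
        _, _, fit = fitted_panel
        report = predict.evaluate_predictions(fit, {})
        assert report.empty()
        assert (report.confusion["O"].to_numpy() == 0).all()

    def test_confusion_rows_sum_to_n(self, design, fitted_panel):
        panel, _, fit = fitted_panel
        vectors = {
            (s, "O"): predict.resample_vectors(panel.rel, panel.det, design, s, "O", n=7, seed=2)
            for s in STAGES
        }
        report = predict.evaluate_predictions(fit, vectors)
        assert (report.confusion["O"].sum(axis=1) == 7).all()

    def test_unknown_variant_rejected(self, fitted_panel):
        _, _, fit = fitted_panel
        with pytest.raises(InvalidArgument):
            predict.evaluate_predictions(fit, {}, variant="bogus")

    def test_plot_writes_file(self, tmp_path, design, fitted_panel):
        panel, _, fit = fitted_panel
        vectors = {
            ("PD", "O"): predict.resample_vectors(panel.rel, panel.det, design, "PD", "O", n=5, seed=2)
        }
        report = predict.evaluate_predictions(fit, vectors)
        out = tmp_path / "panels.png"
        predict.plot_posterior_panels(report, str(out))
        assert out.stat().st_size > 0
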