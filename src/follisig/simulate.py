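"""Synthetic data with known ground truth for the follicle-staging pipeline.

Two generators mirror the two data types of the study design:

* :func:`simulate_counts` — a gene x sample RNA-seq count matrix over the
  8 stage x compartment groups plus multi-tissue pools, negative-binomial
  with group-specific means and planted differential expression;
* :func:`simulate_hurdle_panel` — a qPCR-style biomarker panel with
  stage/compartment-specific dropout (detected yes/no) and expression
  levels generated on the fourth-root scale, with per-gene random stage
  and compartment effects whose stage components are correlated.

Every generator is deterministic under its seed and returns a truth object
from which the noiseless part of each simulated value can be reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    COMPARTMENTS,
    MT,
    NO_STAGE,
    STAGES,
    InvalidArgument,
    group_label,
    lcm_groups,
    validate_design,
)

__all__ = [
    "generate_design",
    "CountSimParams",
    "CountTruth",
    "simulate_counts",
    "simulate_marker_counts",
    "HurdleSimParams",
    "HurdlePanel",
    "simulate_hurdle_panel",
]


# ---------------------------------------------------------------------------
# design generation
# ---------------------------------------------------------------------------

def generate_design(n_rep_default: int = 4, pdo_rep: int = 3, n_mt: int = 3) -> pd.DataFrame:
    """Build the factorial sample sheet of the study.

    Eight stage x compartment groups with ``n_rep_default`` replicates each,
    except primordial oocytes (PDO) which get ``pdo_rep``, plus ``n_mt``
    multi-tissue pools.  The defaults reproduce the 31-sample layout
    (3 PDO + 7 groups x 4 + 3 MT).
    """
    if min(n_rep_default, pdo_rep) < 1 or n_mt < 0:
        raise InvalidArgument("replicate counts must be >= 1 and n_mt >= 0")
    rows = []
    for stage, comp in lcm_groups():
        n = pdo_rep if (stage == "PD" and comp == "O") else n_rep_default
        for r in range(1, n + 1):
            rows.append((f"{group_label(stage, comp)}_{r}", comp, stage, r))
    for r in range(1, n_mt + 1):
        rows.append((f"MT_{r}", MT, NO_STAGE, r))
    return validate_design(pd.DataFrame(rows, columns=["sample_id", "compartment", "stage", "replicate"]))


# ---------------------------------------------------------------------------
# negative-binomial count simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountSimParams:
    """Parameters of the NB count simulator.

    ``dispersion`` is the NB overdispersion alpha with Var = mu + alpha*mu^2
    (the convention of the DESeq family); alpha = 0 is the Poisson limit.
    A ``de_fraction`` of genes carry a ``log2_effect`` planted from a
    randomly chosen onset stage onward, in both compartments.
    """

    n_genes: int = 2000
    baseline_mean: float = 100.0
    dispersion: float = 0.2
    de_fraction: float = 0.05
    log2_effect: float = 2.0
    seed: int = 0

    def validate(self) -> "CountSimParams":
        if self.n_genes < 1 or self.baseline_mean <= 0:
            raise InvalidArgument("n_genes and baseline_mean must be positive")
        if self.dispersion < 0:
            raise InvalidArgument("dispersion must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise InvalidArgument("de_fraction must lie in [0, 1]")
        return self


@dataclass(frozen=True)
class CountTruth:
    """Planted truth: per-gene labels and the expected-mean matrix."""

    labels: pd.DataFrame  # index gene; is_de, log2_effect, onset_stage, target_group
    means: pd.DataFrame  # genes x samples expected NB means


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha == 0.0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(size, p)


def simulate_counts(design: pd.DataFrame, params: CountSimParams) -> tuple[pd.DataFrame, CountTruth]:
    """Simulate an integer count matrix with planted stage effects.

    DE genes multiply their mean by ``2**(+-log2_effect)`` for all stages at
    or after a randomly drawn onset stage (PM, SC or SA), in both
    compartments; MT pools sit at baseline throughout.  Exactly
    ``round(de_fraction * n_genes)`` genes are differential.
    """
    design = validate_design(design)
    if design.empty:
        raise InvalidArgument("design is empty")
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = _gene_names(params.n_genes)

    n_de = int(round(params.de_fraction * params.n_genes))
    de_idx = rng.choice(params.n_genes, size=n_de, replace=False)
    is_de = np.zeros(params.n_genes, dtype=bool)
    is_de[de_idx] = True
    onset = np.array([""] * params.n_genes, dtype=object)
    signed_effect = np.zeros(params.n_genes)
    onset[de_idx] = rng.choice(STAGES[1:], size=n_de)
    signed_effect[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * params.log2_effect

    stage_rank = {s: i for i, s in enumerate(STAGES)}
    means = np.full((params.n_genes, len(design)), float(params.baseline_mean))
    for j, row in design.iterrows():
        if row.compartment == MT:
            continue
        rank = stage_rank[row.stage]
        affected = is_de & np.array([o != "" and stage_rank[o] <= rank for o in onset])
        means[affected, j] *= 2.0 ** signed_effect[affected]

    counts = _nb_draw(rng, means, params.dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=design["sample_id"].tolist())
    labels = pd.DataFrame(
        {
            "is_de": is_de,
            "log2_effect": signed_effect,
            "onset_stage": onset,
            "target_group": [""] * params.n_genes,
        },
        index=genes,
    )
    means_df = pd.DataFrame(means, index=genes, columns=counts_df.columns)
    return counts_df, CountTruth(labels=labels, means=means_df)


def simulate_marker_counts(
    design: pd.DataFrame,
    n_genes: int = 500,
    n_markers: int = 3,
    target_groups: tuple[str, ...] = ("PDO",),
    fold: float = 50.0,
    baseline_mean: float = 50.0,
    dispersion: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, CountTruth]:
    """Count matrix with group-specific marker genes planted.

    For each group label in ``target_groups`` (e.g. ``PDO``, ``SAG``),
    ``n_markers`` genes are enriched ``fold``-fold in that group only; all
    other genes — and the markers outside their group, including in the MT
    pools — sit at ``baseline_mean``.  Exercises the specificity filter of
    biomarker selection.
    """
    design = validate_design(design)
    if fold <= 1 or n_markers * len(target_groups) > n_genes:
        raise InvalidArgument("fold must exceed 1 and markers must fit in the panel")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    sample_groups = [group_label(s, c) for s, c in zip(design["stage"], design["compartment"])]

    target_of = np.array([""] * n_genes, dtype=object)
    marker_idx = rng.choice(n_genes, size=n_markers * len(target_groups), replace=False)
    for k, grp in enumerate(target_groups):
        target_of[marker_idx[k * n_markers : (k + 1) * n_markers]] = grp

    means = np.full((n_genes, len(design)), float(baseline_mean))
    for j, grp in enumerate(sample_groups):
        boost = target_of == grp
        means[boost, j] *= fold
    counts = _nb_draw(rng, means, dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=design["sample_id"].tolist())
    labels = pd.DataFrame(
        {
            "is_de": target_of != "",
            "log2_effect": np.where(target_of != "", np.log2(fold), 0.0),
            "onset_stage": [""] * n_genes,
            "target_group": target_of,
        },
        index=genes,
    )
    return counts_df, CountTruth(labels=labels, means=pd.DataFrame(means, index=genes, columns=counts_df.columns))


# ---------------------------------------------------------------------------
# hurdle panel simulation
# ---------------------------------------------------------------------------

def _ar1_cov(var: float, rho: float, k: int) -> np.ndarray:
    idx = np.arange(k)
    return var * rho ** np.abs(idx[:, None] - idx[None, :])


def _single_factor_corr(loadings: np.ndarray) -> np.ndarray:
    """Correlation matrix R = ll' + diag(1 - l^2) from factor loadings."""
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) > 1):
        raise InvalidArgument("factor loadings must lie in [-1, 1]")
    return np.outer(lam, lam) + np.diag(1.0 - lam**2)


def _check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10):
        raise InvalidArgument(f"{name} must be a symmetric matrix")
    if np.linalg.eigvalsh(mat).min() < -1e-8:
        raise InvalidArgument(f"{name} must be positive semidefinite")
    return mat


@dataclass(frozen=True)
class HurdleSimParams:
    """Generative parameters of the two-part biomarker panel.

    Fixed effects are per (stage, compartment) cell: a detection logit for
    the presence part and a mean on the fourth-root scale for the level
    part.  Each gene draws a stage random vector (length 4, shared across
    compartments) and a compartment random vector (length 2) independently
    for the two parts; the stage vectors carry the across-stage correlation
    structure of interest.  Compartment covariances default to diagonal —
    the generator makes no claim about correlation between a gene's oocyte
    and granulosa shifts.
    """

    n_genes: int = 24
    # rows = stages PD..SA, columns = compartments (O, GC)
    detection_logit: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, -0.5], [0.5, 0.0], [0.0, 0.5], [-0.5, 1.0]])
    )
    level_mean: np.ndarray = field(
        default_factory=lambda: np.array([[2.5, 1.6], [2.2, 1.9], [1.9, 2.2], [1.6, 2.5]])
    )
    stage_cov_binary: np.ndarray = field(default_factory=lambda: _ar1_cov(4.0, 0.6, 4))
    stage_cov_level: np.ndarray = field(default_factory=lambda: _ar1_cov(1.0, 0.6, 4))
    cell_cov_binary: np.ndarray = field(default_factory=lambda: 0.25 * np.eye(2))
    cell_cov_level: np.ndarray = field(default_factory=lambda: 0.1 * np.eye(2))
    resid_sd: float = 0.5
    #: correlation between a gene's binary and level effects.  Real panels
    #: drop out where abundance is low, so a gene undetectable at a stage is
    #: also lowly expressed there; 0 decouples the two parts entirely.
    part_coupling: float = 0.95
    #: reuse the PD dropout realization for PM (per compartment/replicate),
    #: so presence/absence is uninformative for that pair by construction —
    #: only meaningful when PD and PM share detection parameters
    share_pd_pm_dropout: bool = False
    seed: int = 0

    def validate(self) -> "HurdleSimParams":
        if self.n_genes < 1:
            raise InvalidArgument("n_genes must be positive")
        if self.resid_sd <= 0:
            raise InvalidArgument("resid_sd must be positive")
        if not 0.0 <= self.part_coupling <= 1.0:
            raise InvalidArgument("part_coupling must lie in [0, 1]")
        for name in ("stage_cov_binary", "stage_cov_level"):
            mat = _check_psd(getattr(self, name), name)
            if mat.shape != (4, 4):
                raise InvalidArgument(f"{name} must be 4x4")
        for name in ("cell_cov_binary", "cell_cov_level"):
            mat = _check_psd(getattr(self, name), name)
            if mat.shape != (2, 2):
                raise InvalidArgument(f"{name} must be 2x2")
        for name in ("detection_logit", "level_mean"):
            if np.asarray(getattr(self, name)).shape != (4, 2):
                raise InvalidArgument(f"{name} must be 4 stages x 2 compartments")
        return self

    # -- panel archetypes used throughout the validation studies ------------

    @classmethod
    def correlated_stages(
        cls,
        corr_pd_pm: float = 0.95,
        corr_pd_sa: float = -0.9,
        corr_pd_sc: float = 0.4,
        binary_var: float = 4.0,
        level_var: float = 1.0,
        seed: int = 0,
        **kwargs,
    ) -> "HurdleSimParams":
        """Panel whose stage random effects follow a single-factor
        correlation structure with the given PD-anchored correlations
        (identical structure in both parts)."""
        corr = _single_factor_corr([1.0, corr_pd_pm, corr_pd_sc, corr_pd_sa])
        return cls(
            stage_cov_binary=binary_var * corr,
            stage_cov_level=level_var * corr,
            seed=seed,
            **kwargs,
        )

    @classmethod
    def separated_panel(cls, seed: int = 0, **kwargs) -> "HurdleSimParams":
        """Strongly stage-discriminating panel: large independent stage
        effects in both parts and tight residuals, so each gene carries an
        essentially unique stage profile."""
        return cls(
            stage_cov_binary=4.0 * np.eye(4),
            stage_cov_level=1.5 * np.eye(4),
            resid_sd=0.35,
            seed=seed,
            **kwargs,
        )

    @classmethod
    def pd_pm_binary_confounded(cls, seed: int = 0, **kwargs) -> "HurdleSimParams":
        """PD and PM are indistinguishable in presence/absence — identical
        detection logits and perfectly correlated binary stage effects —
        while the level part still separates all four stages."""
        lam = np.array([1.0, 1.0, 0.2, -0.2])
        corr = _single_factor_corr(lam)
        logits = np.array([[0.5, 0.0], [0.5, 0.0], [-0.2, 0.6], [-0.8, 1.0]])
        return cls(
            detection_logit=logits,
            stage_cov_binary=4.0 * corr,
            stage_cov_level=1.5 * np.eye(4),
            resid_sd=0.35,
            share_pd_pm_dropout=True,
            seed=seed,
            **kwargs,
        )


@dataclass(frozen=True)
class HurdlePanel:
    """Simulated panel: quantitative and binary views plus full truth.

    ``rel`` holds the relative expression (raw scale, NaN where
    undetected); ``det`` the 0/1 detection table.  ``truth`` carries every
    drawn effect: fixed-effect grids, per-gene stage/compartment vectors
    for both parts, and the noiseless linear predictors (detection logit
    ``eta`` and fourth-root mean ``mu``) per gene x sample.
    """

    rel: pd.DataFrame
    det: pd.DataFrame
    truth: dict


def simulate_hurdle_panel(design: pd.DataFrame, params: HurdleSimParams) -> HurdlePanel:
    """Draw a two-part biomarker panel over the non-MT samples of ``design``.

    Per gene g, stage s, compartment c, replicate k:

    * detection  z ~ Bernoulli(logit^-1(beta_{s,c} + b_{g,s} + u_{g,c}))
    * level      y^(1/4) ~ Normal(mu_{s,c} + b'_{g,s} + u'_{g,c}, resid_sd)
      where z = 1; the recorded quantity is the fourth power, floored at 0
      (Gaussian draws below zero on the fourth-root scale are rare under
      the default effect sizes and are clipped).

    Undetected wells are recorded as missing, never as numeric zeros.
    """
    design = validate_design(design)
    params.validate()
    lcm = design[design["compartment"] != MT].reset_index(drop=True)
    if lcm.empty:
        raise InvalidArgument("design has no stage x compartment samples")
    rng = np.random.default_rng(params.seed)
    genes = _gene_names(params.n_genes)
    s_idx = lcm["stage"].map({s: i for i, s in enumerate(STAGES)}).to_numpy()
    c_idx = lcm["compartment"].map({c: i for i, c in enumerate(COMPARTMENTS)}).to_numpy()

    def cov_sqrt(cov: np.ndarray) -> np.ndarray:
        # symmetric square root; tolerates singular covariances (corr = 1)
        w, vecs = np.linalg.eigh(cov)
        return (vecs * np.sqrt(np.clip(w, 0.0, None))) @ vecs.T

    def coupled_pair(cov_a: np.ndarray, cov_b: np.ndarray, k: int):
        # binary and level effects share a latent factor: genes that drop
        # out at a stage are also lowly expressed there (coupling rho)
        rho = params.part_coupling
        f = rng.standard_normal((params.n_genes, k))
        e_a = rng.standard_normal((params.n_genes, k))
        e_b = rng.standard_normal((params.n_genes, k))
        mix = np.sqrt(1.0 - rho**2)
        return (rho * f + mix * e_a) @ cov_sqrt(cov_a), (rho * f + mix * e_b) @ cov_sqrt(cov_b)

    b_bin, b_lev = coupled_pair(params.stage_cov_binary, params.stage_cov_level, 4)
    u_bin, u_lev = coupled_pair(params.cell_cov_binary, params.cell_cov_level, 2)

    beta = np.asarray(params.detection_logit, dtype=float)
    mu_fix = np.asarray(params.level_mean, dtype=float)
    eta = beta[s_idx, c_idx][None, :] + b_bin[:, s_idx] + u_bin[:, c_idx]
    mu = mu_fix[s_idx, c_idx][None, :] + b_lev[:, s_idx] + u_lev[:, c_idx]

    p_det = 1.0 / (1.0 + np.exp(-eta))
    u_det = rng.random(eta.shape)
    if params.share_pd_pm_dropout:
        # PM wells reuse the dropout uniforms of the matching PD well
        key = {(c, r): j for j, (st, c, r) in enumerate(
            zip(lcm["stage"], lcm["compartment"], lcm["replicate"])) if st == "PD"}
        for j, (st, c, r) in enumerate(zip(lcm["stage"], lcm["compartment"], lcm["replicate"])):
            if st == "PM" and (c, r) in key:
                u_det[:, j] = u_det[:, key[(c, r)]]
    z = u_det < p_det
    y_quarter = rng.normal(mu, params.resid_sd)
    y = np.clip(y_quarter, 0.0, None) ** 4
    y[~z] = np.nan

    cols = lcm["sample_id"].tolist()
    rel = pd.DataFrame(y, index=genes, columns=cols)
    det = pd.DataFrame(z.astype(int), index=genes, columns=cols)
    truth = {
        "detection_logit": beta,
        "level_mean": mu_fix,
        "b_binary": pd.DataFrame(b_bin, index=genes, columns=list(STAGES)),
        "u_binary": pd.DataFrame(u_bin, index=genes, columns=list(COMPARTMENTS)),
        "b_level": pd.DataFrame(b_lev, index=genes, columns=list(STAGES)),
        "u_level": pd.DataFrame(u_lev, index=genes, columns=list(COMPARTMENTS)),
        "eta": pd.DataFrame(eta, index=genes, columns=cols),
        "mu": pd.DataFrame(mu, index=genes, columns=cols),
        "resid_sd": params.resid_sd,
    }
    return HurdlePanel(rel=rel, det=det, truth=truth)
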