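"""Posterior stage prediction from a biomarker observation vector.

Given a fitted hurdle model, a new observation vector for one compartment
(per gene: detected yes/no, and the expression level where detected) is
assigned a posterior probability over the four follicular stages by
empirical-Bayes plug-in:

    P(s | obs)  proportional to  prior(s)
        x  prod_g  p[g,s]^z_g (1 - p[g,s])^(1 - z_g)
        x  prod_{g: z_g = 1}  Normal(y_g^(1/4); mu[g,s], resid_sd)

with p and mu the fitted cell effects (fixed effects plus the gene's
conditional modes).  A binary-only variant drops the Normal level term,
quantifying how much of the signature is carried by presence/absence
alone.  Predictive ability is assessed by the resampling study of the
original design: new vectors are assembled by drawing, per gene, one
observed replicate from the (stage, compartment) cell, 100 vectors per
stage, and scored through the predictive equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .core import COMPARTMENTS, STAGES, InvalidArgument, validate_design
from .hurdle import HurdleFit

__all__ = [
    "ObservationVector",
    "StagePosterior",
    "ResampleReport",
    "posterior_stage",
    "posterior_stage_binary_only",
    "resample_vectors",
    "evaluate_predictions",
    "plot_posterior_panels",
]


@dataclass(frozen=True)
class ObservationVector:
    """One new expression vector: per-gene detection and level for a
    single compartment.  ``y`` must be NaN exactly where ``z`` is 0."""

    compartment: str
    z: pd.Series
    y: pd.Series

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise InvalidArgument(f"compartment must be one of {COMPARTMENTS}")
        if not self.z.index.equals(self.y.index):
            raise InvalidArgument("z and y must share a gene index")
        bad = (self.z == 0) & self.y.notna()
        if bad.any():
            raise InvalidArgument(f"level present for undetected genes: {list(self.y.index[bad])}")


@dataclass(frozen=True)
class StagePosterior:
    """Posterior over {PD, PM, SC, SA} for one observation vector."""

    probs: pd.Series
    prior: pd.Series
    log_evidence: float

    @property
    def predicted(self) -> str:
        # argmax with ties broken toward the earlier stage
        return str(self.probs.index[int(np.argmax(self.probs.to_numpy()))])


def _uniform_prior() -> pd.Series:
    return pd.Series(0.25, index=list(STAGES))


def _stage_loglik(
    fit: HurdleFit, obs: ObservationVector, include_level: bool
) -> np.ndarray:
    ci = COMPARTMENTS.index(obs.compartment)
    logl = np.zeros(4)
    skipped = []
    for gene in obs.z.index:
        if gene not in fit.presence.modes.index:
            skipped.append(gene)
            continue
        p = fit.detection_prob(gene)[:, ci]
        p = np.clip(p, 1e-12, 1 - 1e-12)
        zg = float(obs.z[gene])
        logl += zg * np.log(p) + (1.0 - zg) * np.log1p(-p)
        if include_level and zg == 1:
            mu = fit.level_mean(gene)[:, ci]
            logl += norm.logpdf(float(obs.y[gene]) ** 0.25, loc=mu, scale=fit.resid_sd)
    if skipped:
        import logging

        logging.getLogger(__name__).warning("genes absent from fit skipped: %s", skipped)
    return logl


def _posterior(fit, obs, prior, include_level) -> StagePosterior:
    prior = _uniform_prior() if prior is None else pd.Series(prior, index=list(STAGES))
    if (prior < 0).any() or prior.sum() <= 0:
        raise InvalidArgument("prior must be nonnegative with positive mass")
    prior = prior / prior.sum()
    with np.errstate(divide="ignore"):  # zero prior mass is a valid input
        logpost = _stage_loglik(fit, obs, include_level) + np.log(prior.to_numpy())
    log_ev = float(logsumexp(logpost))
    probs = np.exp(logpost - log_ev)
    return StagePosterior(
        probs=pd.Series(probs / probs.sum(), index=list(STAGES)),
        prior=prior,
        log_evidence=log_ev,
    )


def posterior_stage(fit: HurdleFit, obs: ObservationVector, prior=None) -> StagePosterior:
    """Full predictive equations: presence/absence and level combined."""
    return _posterior(fit, obs, prior, include_level=True)


def posterior_stage_binary_only(
    fit: HurdleFit, obs: ObservationVector, prior=None
) -> StagePosterior:
    """Degraded predictor using only the presence/absence of expression."""
    return _posterior(fit, obs, prior, include_level=False)


def resample_vectors(
    rel: pd.DataFrame,
    det: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    compartment: str,
    n: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[ObservationVector]:
    """Assemble ``n`` new observation vectors from one (stage, compartment)
    cell by drawing, independently per gene, one observed replicate's
    (z, y) pair uniformly at random — z and y always travel together."""
    design = validate_design(design)
    cols = design.loc[
        (design["stage"] == stage) & (design["compartment"] == compartment), "sample_id"
    ].tolist()
    cols = [c for c in cols if c in det.columns]
    if not cols:
        raise InvalidArgument(f"no observed replicates in cell ({stage}, {compartment})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_cell = det.loc[:, cols].to_numpy()
    y_cell = rel.loc[det.index, cols].to_numpy(dtype=float)
    genes = det.index
    out = []
    for _ in range(n):
        pick = rng.integers(0, len(cols), size=len(genes))
        z = z_cell[np.arange(len(genes)), pick]
        y = y_cell[np.arange(len(genes)), pick]
        y = np.where(z == 1, y, np.nan)
        out.append(
            ObservationVector(
                compartment=compartment,
                z=pd.Series(z, index=genes),
                y=pd.Series(y, index=genes),
            )
        )
    return out


@dataclass
class ResampleReport:
    """Aggregated resampling study.

    ``posteriors`` holds one row per scored vector (true stage,
    compartment, the four posterior probabilities, hard call and tie
    flag); ``mean_true_posterior`` the mean posterior assigned to the true
    stage per (compartment, stage); ``confusion`` a per-compartment 4x4
    matrix of hard calls (rows = true stage, columns = predicted).
    """

    posteriors: pd.DataFrame
    mean_true_posterior: pd.DataFrame
    confusion: dict = field(default_factory=dict)
    variant: str = "full"
    n_per_cell: dict = field(default_factory=dict)

    def empty(self) -> bool:
        return self.posteriors.empty


def evaluate_predictions(
    fit: HurdleFit,
    vectors: dict,
    variant: str = "full",
    prior=None,
) -> ResampleReport:
    """Score resampled vectors through the predictive equations.

    ``vectors`` maps (stage, compartment) to a list of
    :class:`ObservationVector` whose true stage is the key's.
    ``variant`` is ``"full"`` or ``"binary"``.
    """
    if variant not in ("full", "binary"):
        raise InvalidArgument("variant must be 'full' or 'binary'")
    score = posterior_stage if variant == "full" else posterior_stage_binary_only
    rows = []
    for (stage, comp), vecs in vectors.items():
        for vec in vecs:
            post = score(fit, vec, prior=prior)
            probs = post.probs.to_numpy()
            tie = bool(np.sum(probs == probs.max()) > 1)
            rows.append((stage, comp, *probs, post.predicted, tie))
    cols = ["true_stage", "compartment", *[f"P_{s}" for s in STAGES], "predicted", "tie"]
    posteriors = pd.DataFrame(rows, columns=cols)

    if posteriors.empty:
        mean_true = pd.DataFrame(index=list(STAGES), columns=list(COMPARTMENTS), dtype=float)
        confusion = {
            c: pd.DataFrame(0, index=list(STAGES), columns=list(STAGES)) for c in COMPARTMENTS
        }
    else:
        mean_true = pd.DataFrame(index=list(STAGES), columns=list(COMPARTMENTS), dtype=float)
        confusion = {}
        for comp in COMPARTMENTS:
            sub = posteriors[posteriors["compartment"] == comp]
            mat = pd.DataFrame(0, index=list(STAGES), columns=list(STAGES))
            for stage in STAGES:
                cell = sub[sub["true_stage"] == stage]
                if len(cell):
                    mean_true.loc[stage, comp] = float(cell[f"P_{stage}"].mean())
                    mat.loc[stage] = cell["predicted"].value_counts().reindex(STAGES).fillna(0).astype(int).to_numpy()
            confusion[comp] = mat
    return ResampleReport(
        posteriors=posteriors,
        mean_true_posterior=mean_true,
        confusion=confusion,
        variant=variant,
        n_per_cell={k: len(v) for k, v in vectors.items()},
    )


def plot_posterior_panels(report: ResampleReport, path: str) -> None:
    """Strip plot of posterior probabilities per true stage, one panel row
    per compartment — the layout of the study's predictive-power figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(0)  # jitter only
    fig, axes = plt.subplots(2, 4, figsize=(12, 6), sharey=True)
    for r, comp in enumerate(COMPARTMENTS):
        for c, true_stage in enumerate(STAGES):
            ax = axes[r, c]
            sub = report.posteriors[
                (report.posteriors["compartment"] == comp)
                & (report.posteriors["true_stage"] == true_stage)
            ]
            for x, s in enumerate(STAGES):
                vals = sub[f"P_{s}"].to_numpy()
                ax.scatter(x + rng.uniform(-0.15, 0.15, len(vals)), vals, s=6, alpha=0.5)
            ax.set_xticks(range(4), STAGES)
            ax.set_ylim(-0.05, 1.05)
            if r == 0:
                ax.set_title(f"true {true_stage}")
            if c == 0:
                ax.set_ylabel(f"{comp}\nposterior probability")
    fig.suptitle(f"Posterior stage probabilities ({report.variant} model)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
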