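"""Two-part hierarchical model of biomarker expression across follicle stages.

The panel is modelled in two independent parts, sharing a random-effect
architecture but no parameters:

* presence part — detection of gene g in stage s, compartment c,
  replicate k is Bernoulli with
  ``logit p = beta[s,c] + b[g,s] + u[g,c]``,
  where per gene ``b ~ MVN(0, Sigma_stage)`` (4x4, unstructured, carrying
  the across-stage correlations of interest) and ``u ~ MVN(0, diag(tau^2))``
  (compartment shifts; diagonal by default for identifiability of the
  stage/compartment decomposition, full 2x2 behind a flag);

* level part — where detected, the fourth root of the normalized relative
  expression is Gaussian, ``y^(1/4) = mu[s,c] + b'[g,s] + u'[g,c] + eps``,
  with its own stage and compartment covariances and residual sd.  Cells
  in which no replicate was detected contribute a single augmented
  zero-expression record.

Estimation: the Gaussian part by exact maximum likelihood via EM on the
per-gene random effects; the logistic part by Laplace-approximated ML —
penalized joint Newton for the fixed effects and conditional modes (the
fixed effects are profiled within the penalized problem, as in the
standard GLMM Laplace implementations), with the covariances updated by
EM on the conditional modes and their Laplace curvatures, accepting only
steps that do not decrease the Laplace objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import COMPARTMENTS, MT, STAGES, InvalidArgument, validate_design

__all__ = [
    "FitConfig",
    "PartFit",
    "HurdleFit",
    "augment_null_expression",
    "fit_presence_model",
    "fit_level_model",
    "fit_hurdle",
    "stage_effect_correlations",
    "random_effect_significance",
    "laplace_marginal_loglik",
]

logger = logging.getLogger(__name__)

CELLS: list[tuple[str, str]] = [(s, c) for c in COMPARTMENTS for s in STAGES]
CELL_LABELS: list[str] = [f"{s}:{c}" for s, c in CELLS]

_JITTER = 1e-10


# ---------------------------------------------------------------------------
# random-effect structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Structure:
    """Which per-gene random-effect blocks are present.

    ``stage_plus_cell`` is the default additive decomposition (4-dim stage
    vector + 2-dim compartment vector); ``unstructured`` replaces it with
    a free 8x8 covariance over the stage x compartment cells.
    """

    kind: str = "stage_plus_cell"
    full_cell_cov: bool = False

    @property
    def dim(self) -> int:
        return {"stage_plus_cell": 6, "stage_only": 4, "cell_only": 2, "none": 0, "unstructured": 8}[
            self.kind
        ]

    @property
    def labels(self) -> list[str]:
        if self.kind == "stage_plus_cell":
            return list(STAGES) + list(COMPARTMENTS)
        if self.kind == "stage_only":
            return list(STAGES)
        if self.kind == "cell_only":
            return list(COMPARTMENTS)
        if self.kind == "unstructured":
            return list(CELL_LABELS)
        return []

    @property
    def n_cov_params(self) -> int:
        if self.kind == "stage_plus_cell":
            return 10 + (3 if self.full_cell_cov else 2)
        return {"stage_only": 10, "cell_only": 3 if self.full_cell_cov else 2, "none": 0, "unstructured": 36}[
            self.kind
        ]

    def z_row(self, s: int, c: int) -> np.ndarray:
        row = np.zeros(self.dim)
        if self.kind == "stage_plus_cell":
            row[s] = 1.0
            row[4 + c] = 1.0
        elif self.kind == "stage_only":
            row[s] = 1.0
        elif self.kind == "cell_only":
            row[c] = 1.0
        elif self.kind == "unstructured":
            row[c * 4 + s] = 1.0
        return row

    def z_matrix(self, s_idx: np.ndarray, c_idx: np.ndarray) -> np.ndarray:
        return np.array([self.z_row(s, c) for s, c in zip(s_idx, c_idx)])

    def project(self, s_mat: np.ndarray) -> np.ndarray:
        """Constrained M-step: keep the blocks the structure allows."""
        g = np.zeros_like(s_mat)
        s_mat = (s_mat + s_mat.T) / 2.0
        if self.kind == "stage_plus_cell":
            g[:4, :4] = s_mat[:4, :4]
            if self.full_cell_cov:
                g[4:, 4:] = s_mat[4:, 4:]
            else:
                g[4:, 4:] = np.diag(np.diag(s_mat[4:, 4:]))
        elif self.kind in ("stage_only", "unstructured"):
            g = s_mat
        elif self.kind == "cell_only":
            g = s_mat if self.full_cell_cov else np.diag(np.diag(s_mat))
        return g


def _sym_inv_logdet(g: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a PSD matrix with eigenvalue flooring,
    so a boundary covariance (correlation 1, vanishing variance) stays usable."""
    if g.size == 0:
        return g, 0.0
    w, v = np.linalg.eigh((g + g.T) / 2.0)
    floor = max(_JITTER, w.max() * 1e-12) if w.max() > 0 else _JITTER
    w = np.maximum(w, floor)
    inv = (v / w) @ v.T
    return inv, float(np.sum(np.log(w)))


# ---------------------------------------------------------------------------
# fit containers
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    structure: str = "stage_plus_cell"
    full_cell_cov: bool = False
    max_outer: int = 500
    outer_tol: float = 1e-7
    max_inner: int = 200
    inner_tol: float = 1e-9
    ridge: float = 1e-4  # engaged only on detected separation (presence part)
    logit_ceiling: float = 12.0


@dataclass
class PartFit:
    """One part of the hurdle model (presence or level)."""

    part: str  # "presence" | "level"
    structure: str
    beta: pd.Series  # fixed effect per stage:compartment cell
    beta_se: pd.Series
    cov: pd.DataFrame  # random-effect covariance G (structure-projected)
    modes: pd.DataFrame  # per-gene conditional modes, columns = RE labels
    mode_cov: np.ndarray  # (n_genes, q, q) conditional covariances
    loglik: float  # marginal (level) / Laplace (presence) log-likelihood
    resid_sd: float | None = None
    converged: bool = False
    n_iter: int = 0
    separation: bool = False
    ridge_used: float = 0.0
    loglik_trace: list = field(default_factory=list)

    def _struct(self) -> _Structure:
        return _Structure(self.structure)

    def cell_effects(self, gene: str) -> np.ndarray:
        """Linear predictor grid (4 stages x 2 compartments) for one gene:
        fixed effect plus that gene's conditional-mode contributions."""
        st = self._struct()
        v = self.modes.loc[gene].to_numpy() if st.dim else np.zeros(0)
        out = np.empty((4, 2))
        for s in range(4):
            for c in range(2):
                out[s, c] = self.beta.iloc[c * 4 + s] + (st.z_row(s, c) @ v if st.dim else 0.0)
        return out

    @property
    def stage_cov(self) -> np.ndarray | None:
        if self.structure in ("stage_plus_cell", "stage_only"):
            return self.cov.to_numpy()[:4, :4]
        return None


@dataclass
class HurdleFit:
    """Bundle of the two independently fitted parts over a shared panel."""

    presence: PartFit
    level: PartFit
    genes: list[str]

    def detection_prob(self, gene: str) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.presence.cell_effects(gene)))

    def level_mean(self, gene: str) -> np.ndarray:
        """Fourth-root-scale expected level per stage x compartment."""
        return self.level.cell_effects(gene)

    @property
    def resid_sd(self) -> float:
        return float(self.level.resid_sd)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _sample_indices(design: pd.DataFrame, columns) -> tuple[np.ndarray, np.ndarray, list[str]]:
    design = validate_design(design)
    lcm = design[design["compartment"] != MT]
    cols = [c for c in columns if c in set(lcm["sample_id"])]
    if not cols:
        raise InvalidArgument("no stage x compartment samples shared by table and design")
    meta = lcm.set_index("sample_id").loc[cols]
    s_idx = meta["stage"].map({s: i for i, s in enumerate(STAGES)}).to_numpy()
    c_idx = meta["compartment"].map({c: i for i, c in enumerate(COMPARTMENTS)}).to_numpy()
    return s_idx, c_idx, cols


def _cell_design(s_idx: np.ndarray, c_idx: np.ndarray) -> np.ndarray:
    x = np.zeros((len(s_idx), 8))
    x[np.arange(len(s_idx)), c_idx * 4 + s_idx] = 1.0
    return x


def augment_null_expression(
    rel: pd.DataFrame, det: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Long-format level dataset with single zero records for silent cells.

    Detected wells pass through with their raw relative expression.  For
    every (gene, stage, compartment) cell in which *no* replicate was
    detected, exactly one record with null expression (y = 0) is appended,
    flagged ``augmented``; cells with any detection get no filler.
    """
    if not rel.index.equals(det.index) or not rel.columns.equals(det.columns):
        raise InvalidArgument("rel and det tables must be aligned")
    s_idx, c_idx, cols = _sample_indices(design, rel.columns)
    rows = []
    for gene in rel.index:
        z = det.loc[gene, cols].to_numpy()
        y = rel.loc[gene, cols].to_numpy(dtype=float)
        for j, sid in enumerate(cols):
            if z[j]:
                if np.isnan(y[j]):
                    raise InvalidArgument(f"detected well ({gene}, {sid}) has no expression value")
                rows.append((gene, sid, STAGES[s_idx[j]], COMPARTMENTS[c_idx[j]], y[j], False))
        for s in range(4):
            for c in range(2):
                cell = (s_idx == s) & (c_idx == c)
                if cell.any() and not z[cell].any():
                    rows.append((gene, "", STAGES[s], COMPARTMENTS[c], 0.0, True))
    return pd.DataFrame(
        rows, columns=["gene", "sample_id", "stage", "compartment", "y", "augmented"]
    )


# ---------------------------------------------------------------------------
# level part: exact-ML EM for the Gaussian mixed model
# ---------------------------------------------------------------------------

def fit_level_model(
    augmented: pd.DataFrame,
    config: FitConfig | None = None,
) -> PartFit:
    """Fit the Gaussian part on fourth-root levels by EM maximum likelihood.

    ``augmented`` is the output of :func:`augment_null_expression`.  Each
    EM iteration computes the exact per-gene posterior of the random
    effects and updates the fixed cell means, the structured covariance
    and the residual variance; the marginal log-likelihood is monotone.
    """
    cfg = config or FitConfig()
    st = _Structure(cfg.structure, cfg.full_cell_cov)
    df = augmented
    if df.empty:
        raise InvalidArgument("empty level dataset")
    genes = list(pd.unique(df["gene"]))
    s_idx = df["stage"].map({s: i for i, s in enumerate(STAGES)}).to_numpy()
    c_idx = df["compartment"].map({c: i for i, c in enumerate(COMPARTMENTS)}).to_numpy()
    yq = np.asarray(df["y"], dtype=float) ** 0.25
    x_all = _cell_design(s_idx, c_idx)
    if len(yq) < 8:
        raise InvalidArgument("fewer observations than fixed effects")
    z_all = st.z_matrix(s_idx, c_idx) if st.dim else np.zeros((len(yq), 0))
    gene_rows = {g: np.flatnonzero(df["gene"].to_numpy() == g) for g in genes}

    q = st.dim
    beta, *_ = np.linalg.lstsq(x_all, yq, rcond=None)
    resid = yq - x_all @ beta
    sigma2 = max(float(np.var(resid)), 1e-12)
    g_cov = np.eye(q) * max(sigma2, 0.1) if q else np.zeros((0, 0))

    modes = np.zeros((len(genes), q))
    mode_cov = np.zeros((len(genes), q, q))
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_outer + 1):
        g_inv, _ = _sym_inv_logdet(g_cov)
        # E-step: exact Gaussian posterior per gene
        xtx = np.zeros((8, 8))
        xty = np.zeros(8)
        s_accum = np.zeros((q, q))
        rss = 0.0
        tr_zvz = 0.0
        for gi, g in enumerate(genes):
            rows = gene_rows[g]
            xg, zg, yg = x_all[rows], z_all[rows], yq[rows]
            if q:
                a = zg.T @ zg / sigma2 + g_inv
                v = np.linalg.inv(a + _JITTER * np.eye(q))
                m = v @ zg.T @ (yg - xg @ beta) / sigma2
            else:
                v = np.zeros((0, 0))
                m = np.zeros(0)
            modes[gi], mode_cov[gi] = m, v
            s_accum += np.outer(m, m) + v
            fitted = xg @ beta + (zg @ m if q else 0.0)
            rss += float(((yg - fitted) ** 2).sum())
            if q:
                tr_zvz += float(np.einsum("ij,jk,ik->", zg, v, zg))
            xtx += xg.T @ xg
            xty += xg.T @ (yg - (zg @ m if q else 0.0))
        # M-step
        beta = np.linalg.solve(xtx + _JITTER * np.eye(8), xty)
        if q:
            g_cov = st.project(s_accum / len(genes))
        sigma2 = max((rss + tr_zvz) / len(yq), 1e-12)

        ll = _gaussian_marginal_loglik(genes, gene_rows, x_all, z_all, yq, beta, g_cov, sigma2)
        trace.append(ll)
        if it > 1 and abs(trace[-1] - trace[-2]) < cfg.outer_tol * (1 + abs(trace[-2])):
            converged = True
            break

    beta_se = _level_beta_se(genes, gene_rows, x_all, z_all, beta, g_cov, sigma2)
    return PartFit(
        part="level",
        structure=cfg.structure,
        beta=pd.Series(beta, index=CELL_LABELS),
        beta_se=pd.Series(beta_se, index=CELL_LABELS),
        cov=pd.DataFrame(g_cov, index=st.labels, columns=st.labels),
        modes=pd.DataFrame(modes, index=genes, columns=st.labels),
        mode_cov=mode_cov,
        loglik=trace[-1],
        resid_sd=float(np.sqrt(sigma2)),
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
    )


def _gaussian_marginal_loglik(genes, gene_rows, x_all, z_all, yq, beta, g_cov, sigma2) -> float:
    ll = 0.0
    for g in genes:
        rows = gene_rows[g]
        xg, zg, yg = x_all[rows], z_all[rows], yq[rows]
        vy = zg @ g_cov @ zg.T + sigma2 * np.eye(len(rows)) if zg.shape[1] else sigma2 * np.eye(len(rows))
        ll += stats.multivariate_normal.logpdf(yg, mean=xg @ beta, cov=vy, allow_singular=True)
    return float(ll)


def _level_beta_se(genes, gene_rows, x_all, z_all, beta, g_cov, sigma2) -> np.ndarray:
    info = np.zeros((8, 8))
    for g in genes:
        rows = gene_rows[g]
        xg, zg = x_all[rows], z_all[rows]
        vy = zg @ g_cov @ zg.T + sigma2 * np.eye(len(rows)) if zg.shape[1] else sigma2 * np.eye(len(rows))
        info += xg.T @ np.linalg.solve(vy, xg)
    return np.sqrt(np.diag(np.linalg.inv(info + _JITTER * np.eye(8))))


# ---------------------------------------------------------------------------
# presence part: Laplace-approximated ML
# ---------------------------------------------------------------------------

def _penalized_loglik(z_mat, x, z_design, beta, v, g_inv, ridge) -> float:
    eta = x @ beta + (z_design @ v.T).T if v.size else np.tile(x @ beta, (z_mat.shape[0], 1))
    ll = float(np.sum(z_mat * eta - np.logaddexp(0.0, eta)))
    if v.size:
        ll -= 0.5 * float(np.einsum("gi,ij,gj->", v, g_inv, v))
    ll -= 0.5 * ridge * float(beta @ beta)
    return ll


def _pirls(z_mat, x, z_design, beta, v, g_inv, ridge, cfg: FitConfig):
    """Joint penalized Newton over fixed effects and all conditional modes.

    Exploits the shared design across genes: every gene sees the same X
    and Z rows, only its detection vector differs.  Solves the blocked
    Newton system via the Schur complement on the fixed effects.
    """
    n_genes, _ = z_mat.shape
    q = z_design.shape[1]
    obj = _penalized_loglik(z_mat, x, z_design, beta, v, g_inv, ridge)
    for _ in range(cfg.max_inner):
        eta = x @ beta + (z_design @ v.T).T if q else np.tile(x @ beta, (n_genes, 1))
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        r = z_mat - p
        g_beta = x.T @ r.sum(axis=0) - ridge * beta
        h_bb = x.T @ (w.sum(axis=0)[:, None] * x) + ridge * np.eye(8)
        if q:
            g_v = r @ z_design - v @ g_inv
            # per-gene blocks
            schur = h_bb.copy()
            rhs = g_beta.copy()
            bmats = np.empty((n_genes, 8, q))
            hmats = np.empty((n_genes, q, q))
            for gi in range(n_genes):
                wg = w[gi]
                hg = z_design.T @ (wg[:, None] * z_design) + g_inv
                bg = x.T @ (wg[:, None] * z_design)
                hg_inv = np.linalg.inv(hg + _JITTER * np.eye(q))
                schur -= bg @ hg_inv @ bg.T
                rhs -= bg @ hg_inv @ g_v[gi]
                bmats[gi], hmats[gi] = bg, hg_inv
            d_beta = np.linalg.solve(schur, rhs)
            d_v = np.stack([hmats[gi] @ (g_v[gi] - bmats[gi].T @ d_beta) for gi in range(n_genes)])
        else:
            d_beta = np.linalg.solve(h_bb, g_beta)
            d_v = v
        grad_norm = float(np.linalg.norm(g_beta)) + (float(np.linalg.norm(g_v)) if q else 0.0)
        if grad_norm < cfg.inner_tol * (1 + abs(obj)):
            break
        step = 1.0
        for _ in range(30):
            beta_new = beta + step * d_beta
            v_new = v + step * d_v if q else v
            obj_new = _penalized_loglik(z_mat, x, z_design, beta_new, v_new, g_inv, ridge)
            if obj_new >= obj - 1e-12:
                break
            step *= 0.5
        if obj_new < obj - 1e-8 * (1 + abs(obj)):
            break  # no ascent possible
        beta, v, obj = beta_new, (v_new if q else v), obj_new
    return beta, v, obj


def laplace_marginal_loglik(z_mat, x, z_design, beta, v, g_cov, ridge: float = 0.0) -> float:
    """Laplace approximation of the marginal log-likelihood at the given
    fixed effects, conditional modes and random-effect covariance."""
    q = z_design.shape[1]
    g_inv, logdet_g = _sym_inv_logdet(g_cov)
    ll = _penalized_loglik(z_mat, x, z_design, beta, v, g_inv, ridge)
    if not q:
        return ll
    eta = x @ beta + (z_design @ v.T).T
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-10, None)
    for gi in range(z_mat.shape[0]):
        hg = z_design.T @ (w[gi][:, None] * z_design) + g_inv
        ll -= 0.5 * (logdet_g + float(np.linalg.slogdet(hg)[1]))
    return ll


def fit_presence_model(
    det: pd.DataFrame,
    design: pd.DataFrame,
    config: FitConfig | None = None,
) -> PartFit:
    """Fit the hierarchical logistic part by Laplace-approximated ML.

    Alternates the joint penalized Newton step (fixed effects +
    conditional modes) with an EM update of the structured covariance from
    the modes and their Laplace curvatures; a covariance update is
    accepted only if the Laplace objective does not decrease (step-halving
    toward the previous covariance otherwise).  Complete separation — a
    stage x compartment cell that is all-detected or all-undetected —
    engages a small ridge on the fixed effects and is flagged.
    """
    cfg = config or FitConfig()
    st = _Structure(cfg.structure, cfg.full_cell_cov)
    s_idx, c_idx, cols = _sample_indices(design, det.columns)
    z_mat = det.loc[:, cols].to_numpy(dtype=float)
    genes = list(det.index)
    if len(genes) < 2 or len(np.unique(s_idx)) < 2:
        raise InvalidArgument("presence model needs >= 2 genes and >= 2 stages")
    if z_mat.min() == z_mat.max():
        separation = True
    else:
        cell_means = [
            z_mat[:, (s_idx == s) & (c_idx == c)].mean()
            for s in np.unique(s_idx)
            for c in np.unique(c_idx)
            if ((s_idx == s) & (c_idx == c)).any()
        ]
        separation = any(m in (0.0, 1.0) for m in cell_means)
    ridge = cfg.ridge if separation else 0.0
    if separation:
        logger.warning("complete separation in a detection cell; ridge %.1e engaged", ridge)

    x = _cell_design(s_idx, c_idx)
    z_design = st.z_matrix(s_idx, c_idx) if st.dim else np.zeros((len(cols), 0))
    q = st.dim

    cell_rate = np.clip(z_mat.mean(axis=0) @ x / np.maximum(x.sum(axis=0), 1), 0.02, 0.98)
    beta = np.log(cell_rate / (1 - cell_rate))
    v = np.zeros((len(genes), q))
    g_cov = np.eye(q) if q else np.zeros((0, 0))

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, cfg.max_outer + 1):
        g_inv, _ = _sym_inv_logdet(g_cov)
        beta, v, _ = _pirls(z_mat, x, z_design, beta, v, g_inv, ridge, cfg)
        ll = laplace_marginal_loglik(z_mat, x, z_design, beta, v, g_cov, ridge)
        if not q:
            trace.append(ll)
            converged = True
            break
        # EM proposal for the covariance from modes + Laplace curvature
        eta = x @ beta + (z_design @ v.T).T
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        s_accum = np.zeros((q, q))
        for gi in range(len(genes)):
            hg = z_design.T @ (w[gi][:, None] * z_design) + g_inv
            s_accum += np.outer(v[gi], v[gi]) + np.linalg.inv(hg + _JITTER * np.eye(q))
        g_prop = st.project(s_accum / len(genes))

        def _try(step: float):
            g_try = g_cov + step * (g_prop - g_cov)
            if np.linalg.eigvalsh((g_try + g_try.T) / 2.0).min() < 0:
                return None
            g_inv_try, _ = _sym_inv_logdet(g_try)
            beta_t, v_t, _ = _pirls(z_mat, x, z_design, beta.copy(), v.copy(), g_inv_try, ridge, cfg)
            return g_try, beta_t, v_t, laplace_marginal_loglik(z_mat, x, z_design, beta_t, v_t, g_try, ridge)

        accepted = None
        step = 1.0
        for _ in range(8):  # halve toward the previous covariance if needed
            cand = _try(step)
            if cand is not None and cand[3] >= ll - 1e-10 * (1 + abs(ll)):
                accepted = cand
                break
            step *= 0.5
        if accepted is not None:
            # over-relaxation: extrapolate along the accepted EM direction
            while step < 8.0:
                cand = _try(step * 2.0)
                if cand is None or cand[3] < accepted[3]:
                    break
                accepted = cand
                step *= 2.0
            g_cov, beta, v, ll = accepted
        trace.append(ll)
        if it > 1 and abs(trace[-1] - trace[-2]) < cfg.outer_tol * (1 + abs(trace[-2])):
            converged = True
            break
        if accepted is None:
            converged = True
            break

    if np.any(np.abs(beta) > cfg.logit_ceiling) and not separation:
        separation = True
        logger.warning("fixed-effect logits exceeded ceiling; flagging quasi-separation")

    # SEs from the Schur complement of the joint penalized Hessian
    eta = x @ beta + (z_design @ v.T).T if q else np.tile(x @ beta, (len(genes), 1))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-10, None)
    h_bb = x.T @ (w.sum(axis=0)[:, None] * x) + ridge * np.eye(8)
    g_inv, _ = _sym_inv_logdet(g_cov)
    mode_cov = np.zeros((len(genes), q, q))
    schur = h_bb.copy()
    for gi in range(len(genes)):
        if q:
            hg = z_design.T @ (w[gi][:, None] * z_design) + g_inv
            hg_inv = np.linalg.inv(hg + _JITTER * np.eye(q))
            mode_cov[gi] = hg_inv
            bg = x.T @ (w[gi][:, None] * z_design)
            schur -= bg @ hg_inv @ bg.T
    beta_se = np.sqrt(np.diag(np.linalg.inv(schur + _JITTER * np.eye(8))))

    return PartFit(
        part="presence",
        structure=cfg.structure,
        beta=pd.Series(beta, index=CELL_LABELS),
        beta_se=pd.Series(beta_se, index=CELL_LABELS),
        cov=pd.DataFrame(g_cov, index=st.labels, columns=st.labels),
        modes=pd.DataFrame(v, index=genes, columns=st.labels),
        mode_cov=mode_cov,
        loglik=trace[-1],
        converged=converged,
        n_iter=it,
        separation=separation,
        ridge_used=ridge,
        loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# bundling, reports, diagnostics
# ---------------------------------------------------------------------------

def fit_hurdle(
    det: pd.DataFrame,
    rel: pd.DataFrame,
    design: pd.DataFrame,
    config: FitConfig | None = None,
) -> HurdleFit:
    """Fit both parts on the common gene panel; the parts share no
    parameters and are estimated independently."""
    genes = det.index.intersection(rel.index)
    if genes.empty:
        raise InvalidArgument("no genes shared between detection and level tables")
    det = det.loc[genes]
    rel = rel.loc[genes, det.columns]
    presence = fit_presence_model(det, design, config)
    level = fit_level_model(augment_null_expression(rel, det, design), config)
    return HurdleFit(presence=presence, level=level, genes=list(genes))


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(d, d)
    corr[~np.isfinite(corr)] = np.nan  # zero-variance components are undefined
    np.fill_diagonal(corr, np.where(d > 0, 1.0, np.nan))
    return corr


def stage_effect_correlations(fit: HurdleFit) -> dict:
    """Across-stage correlation report for both parts.

    ``overall`` converts the estimated stage covariance to a correlation
    matrix; ``within`` gives, per compartment, the empirical correlation
    across genes of the conditional-mode stage profiles
    b_hat[g, s] + u_hat[g, c].
    """
    report: dict = {}
    for part in (fit.presence, fit.level):
        entry: dict = {}
        sc = part.stage_cov
        entry["overall"] = (
            pd.DataFrame(_cov_to_corr(sc), index=STAGES, columns=STAGES) if sc is not None else None
        )
        within = {}
        if part.structure == "stage_plus_cell":
            b = part.modes[list(STAGES)].to_numpy()
            for ci, comp in enumerate(COMPARTMENTS):
                u = part.modes[comp].to_numpy()
                prof = b + u[:, None]
                within[comp] = pd.DataFrame(
                    _cov_to_corr(np.cov(prof.T)), index=STAGES, columns=STAGES
                )
        entry["within"] = within
        report[part.part] = entry
    return report


def random_effect_significance(
    det: pd.DataFrame | None,
    augmented: pd.DataFrame | None,
    design: pd.DataFrame,
    part: str = "presence",
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio diagnostics of each variance component.

    Refits with the stage (resp. compartment) block removed and refers
    twice the log-likelihood drop to chi-square with the number of freed
    covariance parameters — conservative at the boundary of the parameter
    space, which only understates the significance it reports.
    """
    cfg = config or FitConfig()
    if cfg.structure != "stage_plus_cell":
        raise InvalidArgument("component tests are defined for the stage_plus_cell structure")

    def _fit(kind: str) -> float:
        sub = FitConfig(**{**cfg.__dict__, "structure": kind})
        if part == "presence":
            return fit_presence_model(det, design, sub).loglik
        return fit_level_model(augmented, sub).loglik

    ll_full = _fit("stage_plus_cell")
    rows = []
    for name, reduced, df_free in (("stage", "cell_only", 10), ("compartment", "stage_only", 2)):
        ll_red = _fit(reduced)
        lrt = max(0.0, 2.0 * (ll_full - ll_red))
        rows.append((name, lrt, df_free, float(stats.chi2.sf(lrt, df_free))))
    return pd.DataFrame(rows, columns=["component", "lrt", "df", "pval"])
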