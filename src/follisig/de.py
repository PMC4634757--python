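"""Negative-binomial differential expression and biomarker selection.

The engine mirrors the classical count-based DE workflow for a small
factorial design: median-of-ratios size factors, method-of-moments
dispersion pooled across stage x compartment groups, a conditional exact
test on group sums for pairwise contrasts, and a likelihood-ratio test of
``count ~ stage`` against ``count ~ 1`` fitted per compartment as NB GLMs.

Selection rules implemented on top of the tests:

* stage-regulated genes: GLM FDR < 5% AND some pairwise p < 1% AND
  fold change > 2;
* compartment/stage biomarkers: target group vs all remaining samples
  (multi-tissue pools included) at FDR < 5% with fold change > 3 for
  granulosa targets and > 10 for oocyte targets.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logsumexp

from .core import COMPARTMENTS, STAGES, InvalidArgument, group_label, validate_design

__all__ = [
    "size_factors",
    "normalized_counts",
    "estimate_dispersion",
    "nb_exact_test",
    "nb_glm_lrt",
    "bh_adjust",
    "compartment_stage_de",
    "select_stage_de",
    "select_biomarkers",
    "transition_summary",
]

logger = logging.getLogger(__name__)

_POISSON_EPS = 1e-12
_TIE_REL_TOL = 1e-8  # partitions whose probability ties the observed one count as extreme

TRANSITIONS: tuple[tuple[str, str], ...] = (("PD", "PM"), ("PM", "SC"), ("SC", "SA"))


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Each sample's factor is the median over genes of its count divided by
    that gene's geometric mean across samples, using genes with nonzero
    counts everywhere.  If no such gene exists, ``allow_pseudo_reference``
    falls back to genes nonzero in at least half the samples.
    """
    mat = counts.to_numpy(dtype=float)
    usable = (mat > 0).all(axis=1)
    if not usable.any():
        if not allow_pseudo_reference:
            raise InvalidArgument(
                "no gene has nonzero counts in every sample; "
                "rerun with allow_pseudo_reference=True"
            )
        usable = (mat > 0).mean(axis=1) >= 0.5
        if not usable.any():
            raise InvalidArgument("counts too sparse for size-factor estimation")
    sub = mat[usable]
    with np.errstate(divide="ignore"):
        log_geo = np.where((sub > 0).all(axis=1), np.log(np.where(sub > 0, sub, 1.0)).mean(axis=1), np.nan)
    ratios = np.log(np.where(sub > 0, sub, np.nan)) - log_geo[:, None]
    sf = np.exp(np.nanmedian(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts / sf


def estimate_dispersion(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    floor: float = 1e-8,
    share: str = "maximum",
) -> pd.Series:
    """Per-gene NB dispersion alpha by pooled method of moments.

    Within each stage x compartment group with >= 2 replicates, the excess
    of the normalized-count variance over its Poisson shot noise is scaled
    by the squared group mean, alpha_g = (v_g - m_g * c_g) / m_g^2 with
    c_g the group mean of 1/size_factor; the per-gene estimate pools the
    group alphas weighted by residual degrees of freedom, then clamps at
    ``floor``.  Scaling group by group keeps the estimate consistent when
    group means differ (strong regulation must not masquerade as
    overdispersion).

    With few replicates the gene-wise moment estimate is noisy and its
    underestimates make every downstream test anti-conservative, so by
    default (``share="maximum"``) each gene uses the larger of its own
    estimate and a mean-dispersion trend alpha(mu) = a0 + a1/mu fitted
    across genes; ``share="none"`` keeps the raw gene-wise values.
    """
    if share not in ("maximum", "none"):
        raise InvalidArgument("share must be 'maximum' or 'none'")
    design = validate_design(design)
    sf = size_factors(counts)
    norm = normalized_counts(counts, sf).to_numpy(dtype=float)
    groups = [group_label(s, c) for s, c in zip(design["stage"], design["compartment"])]
    cols = pd.Index(design["sample_id"])
    order = [counts.columns.get_loc(s) for s in cols]
    norm = norm[:, order]
    inv_sf = (1.0 / sf.loc[cols]).to_numpy()

    alpha_num = np.zeros(norm.shape[0])
    dof_tot = 0.0
    weight = np.zeros(norm.shape[0])
    for g in sorted(set(groups)):
        idx = [i for i, lab in enumerate(groups) if lab == g]
        if len(idx) < 2:
            continue
        block = norm[:, idx]
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        c = float(inv_sf[idx].mean())
        dof = len(idx) - 1
        dof_tot += dof
        ok = m > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m * c) / m**2
        alpha_num[ok] += dof * a[ok]
        weight[ok] += dof
    if dof_tot == 0:
        raise InvalidArgument("dispersion needs >= 2 replicates in at least one group")
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = alpha_num / weight
    alpha = np.where(np.isfinite(alpha), alpha, floor)
    if share == "maximum":
        base_mean = norm.mean(axis=1)
        ok = (base_mean > 0) & (alpha > floor)
        if ok.sum() >= 10:
            design_mat = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
            coef, *_ = np.linalg.lstsq(design_mat, alpha[ok], rcond=None)
            with np.errstate(divide="ignore"):
                trend = np.clip(coef[0] + coef[1] / np.maximum(base_mean, 1e-12), 0.0, None)
            alpha = np.maximum(alpha, trend)
    return pd.Series(np.maximum(alpha, floor), index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _group_sum_logpmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    """log pmf of a group's count sum, NB moment-matched to (mean, var)."""
    if mean <= 0:
        out = np.full(k.shape, -np.inf)
        out[k == 0] = 0.0
        return out
    if var <= mean * (1 + _POISSON_EPS):
        return stats.poisson.logpmf(k, mean)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(
    counts_a,
    counts_b,
    sf_a,
    sf_b,
    alpha: float,
) -> float:
    """Conditional two-sided NB exact test on the two group sums.

    Under the null of a common normalized mean q0, the group sums K_A and
    K_B are modelled as NB variables moment-matched to mean q0*sum(s) and
    variance q0*sum(s) + alpha*q0^2*sum(s^2).  Conditioning on the total
    K = K_A + K_B, the p-value is the probability mass of all partitions
    (k, K-k) no more likely than the observed one, relative to the total
    mass — two-sidedness by summing low-probability partitions rather than
    doubling a tail.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgument("both groups must be nonempty")
    sa = np.asarray(sf_a, dtype=float)
    sb = np.asarray(sf_b, dtype=float)
    ka, kb = a.sum(), b.sum()
    total = int(round(ka + kb))
    if total == 0:
        return 1.0
    q0 = (ka + kb) / (sa.sum() + sb.sum())
    mean_a, mean_b = q0 * sa.sum(), q0 * sb.sum()
    var_a = mean_a + alpha * q0**2 * (sa**2).sum()
    var_b = mean_b + alpha * q0**2 * (sb**2).sum()

    ks = np.arange(total + 1)
    logp = _group_sum_logpmf(ks, mean_a, var_a) + _group_sum_logpmf(ks[::-1], mean_b, var_b)
    log_obs = _group_sum_logpmf(np.array([ka]), mean_a, var_a)[0] + _group_sum_logpmf(
        np.array([kb]), mean_b, var_b
    )[0]
    keep = logp <= log_obs + np.log1p(_TIE_REL_TOL)
    if not keep.any():
        return 1.0
    pval = float(np.exp(logsumexp(logp[keep]) - logsumexp(logp)))
    return min(1.0, pval)


def nb_glm_lrt(
    counts_gene,
    stages,
    sf,
    alpha: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> float:
    """Likelihood-ratio test of ``count ~ stage`` against ``count ~ 1``.

    Both models are NB log-link GLMs with fixed dispersion and
    log-size-factor offsets, fitted by IRLS; the statistic is referred to
    chi-square with (number of stages - 1) degrees of freedom.  Returns
    NaN (with a log message) if either fit fails to converge.
    """
    y = np.asarray(counts_gene, dtype=float)
    stages = np.asarray(stages)
    levels = pd.unique(stages)
    if len(levels) < 2:
        raise InvalidArgument("likelihood-ratio test needs >= 2 stages")
    offset = np.log(np.asarray(sf, dtype=float))
    fam = (
        sm.families.Poisson()
        if alpha <= _POISSON_EPS
        else sm.families.NegativeBinomial(alpha=float(alpha))
    )
    x_full = pd.get_dummies(pd.Series(stages), drop_first=True, dtype=float)
    x_full.insert(0, "const", 1.0)
    x_null = np.ones((y.size, 1))
    try:
        fit_full = sm.GLM(y, x_full.to_numpy(), family=fam, offset=offset).fit(
            maxiter=max_iter, tol=tol
        )
        fit_null = sm.GLM(y, x_null, family=fam, offset=offset).fit(maxiter=max_iter, tol=tol)
    except Exception as exc:  # pragma: no cover - rare numerical failure
        logger.warning("GLM fit failed: %s", exc)
        return float("nan")
    lrt = 2.0 * (fit_full.llf - fit_null.llf)
    return float(stats.chi2.sf(max(lrt, 0.0), df=len(levels) - 1))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise InvalidArgument("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[ok] = res
    return out


# ---------------------------------------------------------------------------
# stage-wise DE within a compartment
# ---------------------------------------------------------------------------

def _stage_columns(design: pd.DataFrame, compartment: str) -> dict[str, list[str]]:
    sub = design[design["compartment"] == compartment]
    return {
        s: sub.loc[sub["stage"] == s, "sample_id"].tolist()
        for s in STAGES
        if (sub["stage"] == s).any()
    }


def compartment_stage_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    compartment: str,
    dispersions: pd.Series | None = None,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Full stage-wise DE table for one compartment.

    Per gene: normalized stage means, the GLM likelihood-ratio p-value and
    its BH adjustment over genes, and for every stage pair (s1, s2) the
    exact-test p-value ``p_s1_s2`` and fold change ``fc_s1_s2`` (later
    stage over earlier; x/0 reported as +inf, 0/0 as NaN).
    """
    design = validate_design(design)
    if compartment not in COMPARTMENTS:
        raise InvalidArgument(f"compartment must be one of {COMPARTMENTS}")
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, design)
    by_stage = _stage_columns(design, compartment)
    if len(by_stage) < 2:
        raise InvalidArgument("need >= 2 stages in the compartment")
    stages_present = [s for s in STAGES if s in by_stage]
    all_cols = [c for s in stages_present for c in by_stage[s]]
    stage_of = np.concatenate([[s] * len(by_stage[s]) for s in stages_present])
    norm = normalized_counts(counts, sf)

    out = pd.DataFrame(index=counts.index)
    for s in stages_present:
        out[f"mean_{s}"] = norm[by_stage[s]].mean(axis=1)

    glm_p = np.array(
        [
            nb_glm_lrt(
                counts.loc[g, all_cols].to_numpy(),
                stage_of,
                sf.loc[all_cols].to_numpy(),
                float(dispersions.loc[g]),
            )
            for g in counts.index
        ]
    )
    out["glm_pval"] = glm_p
    out["glm_padj"] = bh_adjust(glm_p)

    for s1, s2 in itertools.combinations(stages_present, 2):
        ca, cb = by_stage[s1], by_stage[s2]
        pvals = np.array(
            [
                nb_exact_test(
                    counts.loc[g, ca].to_numpy(),
                    counts.loc[g, cb].to_numpy(),
                    sf.loc[ca].to_numpy(),
                    sf.loc[cb].to_numpy(),
                    float(dispersions.loc[g]),
                )
                for g in counts.index
            ]
        )
        out[f"p_{s1}_{s2}"] = pvals
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = out[f"mean_{s2}"] / out[f"mean_{s1}"]
        out[f"fc_{s1}_{s2}"] = fc
    return out


def _fc_passes(fc: float, threshold: float) -> bool:
    if not np.isfinite(fc):
        return bool(np.isposinf(fc))  # x/0 passes any threshold; 0/0 (NaN) never
    return fc > threshold or (fc > 0 and fc < 1.0 / threshold)


def select_stage_de(
    de_table: pd.DataFrame,
    glm_fdr: float = 0.05,
    pairwise_p: float = 0.01,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Apply the three selection gates to a :func:`compartment_stage_de`
    table: GLM FDR, best pairwise p, and fold change, all required.

    Returns the selected rows with ``best_pair`` and ``best_pair_p``
    columns appended.
    """
    pair_cols = [c for c in de_table.columns if c.startswith("p_")]
    keep = []
    best_pairs, best_ps = [], []
    for gene, row in de_table.iterrows():
        if not (np.isfinite(row["glm_padj"]) and row["glm_padj"] < glm_fdr):
            continue
        passing = [
            (row[pc], pc[2:])
            for pc in pair_cols
            if np.isfinite(row[pc])
            and row[pc] < pairwise_p
            and _fc_passes(row[f"fc_{pc[2:]}"], fc_threshold)
        ]
        if not passing:
            continue
        p, pair = min(passing)
        keep.append(gene)
        best_pairs.append(pair)
        best_ps.append(p)
    out = de_table.loc[keep].copy()
    out["best_pair"] = best_pairs
    out["best_pair_p"] = best_ps
    return out


# ---------------------------------------------------------------------------
# biomarker selection and transition summaries
# ---------------------------------------------------------------------------

def select_biomarkers(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    target_group: str,
    fc_threshold: float | None = None,
    fdr: float = 0.05,
    dispersions: pd.Series | None = None,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Group-specific biomarkers: target group vs everything else pooled.

    ``target_group`` is a study-style label (PDO ... SAG).  The complement
    pools every other sample — multi-tissue pools included, so a selected
    gene is specific against somatic background too.  Genes pass with BH
    FDR < ``fdr`` and fold change (target over rest) above the threshold
    (default 10 for oocyte targets, 3 for granulosa).  The returned table
    covers all genes with a boolean ``selected`` column.
    """
    design = validate_design(design)
    labels = [group_label(s, c) for s, c in zip(design["stage"], design["compartment"])]
    target_cols = [sid for sid, lab in zip(design["sample_id"], labels) if lab == target_group]
    rest_cols = [sid for sid, lab in zip(design["sample_id"], labels) if lab != target_group]
    if not target_cols:
        raise InvalidArgument(f"no samples in target group {target_group!r}")
    if fc_threshold is None:
        fc_threshold = 10.0 if target_group.endswith("O") else 3.0
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, design)
    norm = normalized_counts(counts, sf)
    mean_target = norm[target_cols].mean(axis=1)
    mean_rest = norm[rest_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_target / mean_rest

    pvals = np.array(
        [
            nb_exact_test(
                counts.loc[g, target_cols].to_numpy(),
                counts.loc[g, rest_cols].to_numpy(),
                sf.loc[target_cols].to_numpy(),
                sf.loc[rest_cols].to_numpy(),
                float(dispersions.loc[g]),
            )
            for g in counts.index
        ]
    )
    padj = bh_adjust(pvals)
    selected = (padj < fdr) & np.array(
        [np.isposinf(f) or (np.isfinite(f) and f > fc_threshold) for f in fc]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc)
    direction = np.where(~selected, "none", np.where(fc > 1, "up", "down"))
    return pd.DataFrame(
        {
            "mean_target": mean_target,
            "mean_rest": mean_rest,
            "fold_change": fc,
            "log2fc": log2fc,
            "pval": pvals,
            "padj": padj,
            "direction": direction,
            "selected": selected,
        },
        index=counts.index,
    )


def transition_summary(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    dispersions: pd.Series | None = None,
    pairwise_p: float = 0.01,
    fc_threshold: float = 2.0,
    de_tables: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Counts of up-/down-regulated genes per consecutive stage transition
    (PD->PM, PM->SC, SC->SA) in each compartment.

    A gene counts as up at a transition when its pairwise exact-test p is
    below ``pairwise_p`` and the later/earlier fold change exceeds
    ``fc_threshold``; down when it falls below 1/threshold.  Precomputed
    :func:`compartment_stage_de` tables can be passed to avoid re-testing.
    """
    if de_tables is None:
        de_tables = {
            comp: compartment_stage_de(counts, design, comp, dispersions=dispersions)
            for comp in COMPARTMENTS
        }
    rows = []
    for comp, table in de_tables.items():
        for s1, s2 in TRANSITIONS:
            pcol, fcol = f"p_{s1}_{s2}", f"fc_{s1}_{s2}"
            if pcol not in table.columns:
                continue
            sig = table[pcol] < pairwise_p
            fc = table[fcol]
            up = int((sig & ((fc > fc_threshold) | np.isposinf(fc))).sum())
            down = int((sig & (fc < 1.0 / fc_threshold)).sum())
            rows.append((comp, f"{s1}->{s2}", up, down))
    return pd.DataFrame(rows, columns=["compartment", "transition", "up", "down"])
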