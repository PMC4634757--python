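"""Efficiency-corrected qPCR quantification and reference normalization.

Implements the standard relative-quantification chain for a biomarker
panel: amplification efficiency from a serial-dilution standard curve
(E = 10^(-1/slope)), efficiency-corrected quantities via the Pfaffl ratio
E^(Ct_calibrator - Ct), normalization by the geometric mean of reference
genes, geNorm-style reference-stability ranking, and detection calling for
undetected wells.

Tables are gene x sample pandas DataFrames; an undetected well is NaN,
never a fabricated number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidArgument, QualityFailure

__all__ = [
    "EfficiencyCurve",
    "fit_efficiency",
    "pfaffl_quantity",
    "pfaffl_table",
    "normalize_by_references",
    "genorm_stability",
    "call_detection",
    "average_technical_replicates",
    "simulate_ct",
]

logger = logging.getLogger(__name__)

#: default detection cutoff in cycles and margin below a negative control
DEFAULT_CYCLE_CUTOFF = 40.0
DEFAULT_CONTROL_MARGIN = 3.0


@dataclass(frozen=True)
class EfficiencyCurve:
    """Standard-curve fit for one assay.

    ``slope`` is in cycles per log10 of relative input; a perfectly
    doubling assay has slope -3.32 and efficiency 2.0.
    """

    gene: str
    dilution_factors: np.ndarray
    ct_values: np.ndarray
    slope: float
    intercept: float
    efficiency: float
    r_squared: float


def fit_efficiency(dilutions, cts, gene: str = "") -> EfficiencyCurve:
    """Least-squares standard curve of Ct on log10(relative input).

    Requires at least three dilution points.  A non-negative slope means
    the assay is not amplifying and raises :class:`QualityFailure`.
    """
    d = np.asarray(dilutions, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if d.size != ct.size or d.size < 3:
        raise InvalidArgument("need >= 3 matched dilution/Ct points")
    if np.any(d <= 0):
        raise InvalidArgument("dilution factors must be strictly positive")
    res = stats.linregress(np.log10(d), ct)
    if res.slope >= 0:
        raise QualityFailure(f"non-amplifying standard curve for {gene!r} (slope {res.slope:.3f})")
    eff = 10.0 ** (-1.0 / res.slope)
    return EfficiencyCurve(
        gene=gene,
        dilution_factors=d,
        ct_values=ct,
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=float(eff),
        r_squared=float(res.rvalue**2),
    )


def pfaffl_quantity(ct, calibrator_ct: float, efficiency: float):
    """Efficiency-corrected relative quantity E^(Ct_calibrator - Ct).

    ``ct`` may be a scalar or array; NaN (undetected) propagates to NaN.
    """
    if efficiency <= 1:
        raise InvalidArgument("efficiency must exceed 1")
    return efficiency ** (calibrator_ct - np.asarray(ct, dtype=float))


def pfaffl_table(
    ct: pd.DataFrame,
    efficiencies: pd.Series | dict,
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Per-gene Pfaffl quantification of a full Ct table.

    The calibrator Ct is the named sample's Ct when ``calibrator`` is
    given, otherwise each gene's mean Ct across its detected samples.
    """
    eff = pd.Series(efficiencies)
    missing = ct.index.difference(eff.index)
    if len(missing):
        raise InvalidArgument(f"no efficiency for genes: {list(missing)}")
    out = pd.DataFrame(np.nan, index=ct.index, columns=ct.columns)
    for gene in ct.index:
        row = ct.loc[gene]
        if calibrator is not None:
            cal = row[calibrator]
            if np.isnan(cal):
                raise InvalidArgument(f"calibrator sample {calibrator!r} undetected for {gene!r}")
        else:
            cal = row.dropna().mean()
        if np.isnan(cal):
            continue  # gene never detected
        out.loc[gene] = pfaffl_quantity(row.to_numpy(), float(cal), float(eff[gene]))
    return out


def normalize_by_references(rel: pd.DataFrame, reference_genes) -> pd.DataFrame:
    """Divide each sample's quantities by the geometric mean of its
    reference-gene quantities.

    Samples in which any reference is undetected cannot be normalized;
    they are dropped with a logged warning.  Reference genes themselves
    are normalized like any target.
    """
    refs = list(reference_genes)
    missing = set(refs) - set(rel.index)
    if missing:
        raise InvalidArgument(f"reference genes absent from table: {sorted(missing)}")
    ref_block = rel.loc[refs]
    ok = ref_block.notna().all(axis=0) & (ref_block > 0).all(axis=0)
    dropped = rel.columns[~ok].tolist()
    if dropped:
        logger.warning("normalization skipped for samples with undetected references: %s", dropped)
    kept = rel.loc[:, ok]
    nf = np.exp(np.log(ref_block.loc[:, ok]).mean(axis=0))
    return kept / nf


def genorm_stability(rel: pd.DataFrame, candidates) -> tuple[pd.Series, list[str]]:
    """geNorm expression-stability measure M and exclusion ranking.

    M_j is the mean, over the other candidates k, of the standard deviation
    across samples of log2(rel_j / rel_k); stable references have low M.
    Only samples in which every candidate is detected are used.  The
    ranking lists genes in exclusion order (least stable first), obtained
    by iteratively dropping the largest-M candidate and recomputing.
    """
    cand = list(candidates)
    if len(cand) < 3:
        raise InvalidArgument("geNorm needs >= 3 candidate references")
    block = rel.loc[cand]
    complete = block.notna().all(axis=0) & (block > 0).all(axis=0)
    if complete.sum() < 2:
        raise InvalidArgument("need >= 2 samples with all candidates detected")
    logb = np.log2(block.loc[:, complete])

    def m_values(names: list[str]) -> pd.Series:
        vals = {}
        for j in names:
            sds = [np.std(logb.loc[j] - logb.loc[k], ddof=1) for k in names if k != j]
            vals[j] = float(np.mean(sds))
        return pd.Series(vals)

    m_full = m_values(cand)
    exclusion: list[str] = []
    remaining = list(cand)
    while len(remaining) > 2:
        m = m_values(remaining)
        worst = m.idxmax()
        exclusion.append(worst)
        remaining.remove(worst)
    exclusion.extend(remaining)  # final pair is tied-best, kept last
    return m_full, exclusion


def call_detection(
    ct: pd.DataFrame,
    cycle_cutoff: float = DEFAULT_CYCLE_CUTOFF,
    negative_controls: pd.Series | dict | None = None,
    control_margin: float = DEFAULT_CONTROL_MARGIN,
) -> pd.DataFrame:
    """Binary detection calls from a Ct table.

    A well is detected (1) iff its Ct is numeric, below ``cycle_cutoff``,
    and — when a per-gene negative control Ct exists — at least
    ``control_margin`` cycles below that control.
    """
    z = ct.notna() & (ct < cycle_cutoff)
    if negative_controls is not None:
        nc = pd.Series(negative_controls)
        for gene in z.index.intersection(nc.index):
            ctrl = nc[gene]
            if not np.isnan(ctrl):
                z.loc[gene] &= ct.loc[gene] <= ctrl - control_margin
    return z.astype(int)


def average_technical_replicates(table: pd.DataFrame, replicate_of: dict) -> pd.DataFrame:
    """Average technical-replicate columns into their biological sample.

    ``replicate_of`` maps each column to its biological sample id; columns
    mapping to the same id are averaged (NaN ignored, all-NaN stays NaN).
    Apply before or after :func:`normalize_by_references` — the two orders
    differ whenever replicates disagree, and neither is canonical.
    """
    missing = set(table.columns) - set(replicate_of)
    if missing:
        raise InvalidArgument(f"columns without a biological sample: {sorted(missing)}")
    return table.T.groupby(pd.Series(replicate_of)).mean().T


def simulate_ct(
    quantities: pd.DataFrame,
    efficiency: float | pd.Series = 2.0,
    calibrator_ct: float = 25.0,
    cycle_cutoff: float = DEFAULT_CYCLE_CUTOFF,
) -> pd.DataFrame:
    """Forward model: Ct values that would yield the given relative
    quantities under the Pfaffl relation, Ct = Ct_cal - log_E(quantity).

    Quantities of 0 or NaN come back as NaN (no amplification before the
    cutoff).  Inverse of :func:`pfaffl_table` with a fixed calibrator.
    """
    eff = pd.Series(efficiency, index=quantities.index) if np.isscalar(efficiency) else pd.Series(efficiency)
    q = quantities.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ct = calibrator_ct - np.log(q) / np.log(eff.to_numpy())[:, None]
    ct[~np.isfinite(ct)] = np.nan
    ct[ct >= cycle_cutoff] = np.nan
    return pd.DataFrame(ct, index=quantities.index, columns=quantities.columns)
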