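"""Negative-binomial differential expression and the piecewise eFC/aeFC
fold-change statistics.

Testing follows the classic count-based recipe: median-of-ratios size
factors, method-of-moments per-transcript dispersions shrunk towards a
fitted 1/mean trend (final dispersion = max(raw, trend)), and a two-sided
exact test that conditions on the two groups' total count under
independent negative-binomial group sums.  Testing runs on raw counts;
fold changes are reported on RPKM via the signed piecewise statistic

    eFC(r1, r2) = sign(r2 - r1) * max(r1, r2) / min(r1, r2)   if min > 0
                = r2 - r1                                     if min = 0

so eFC(r, r) = 0 and eFC is antisymmetric.  A transcript is significant
when its BH-adjusted q < 0.05 and log2|eFC| > 2.  Enzyme-level values
aggregate member transcripts: aeFC = eFC / n with n the number of member
transcripts expressed in either group, and an enzyme is significant when
at least one significant transcript maps to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom, poisson

from .data_model import AnnotatedCounts, ComparisonSpec
from .pathways import bh_adjust
from .quantify import ExpressionMatrix

__all__ = [
    "DispersionModel",
    "size_factors",
    "fit_dispersions",
    "nb_test",
    "efc",
    "call_significant",
    "run_comparison",
    "enzyme_aggregate",
]


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over reference transcripts of count_ij / geometric
    mean_i.  The reference set is the transcripts with all-positive counts;
    when none exists, ``pseudo_reference=True`` falls back to the geometric
    mean over each transcript's positive samples only.
    """
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if all_positive.any():
        ref = arr[all_positive]
        log_geo = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geo[:, None]
    elif pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(arr > 0, np.log(arr), np.nan)
        log_geo = np.nanmean(logs, axis=1)
        ratios = logs - log_geo[:, None]
    else:
        raise ValueError(
            "no transcript has positive counts in every sample; pass "
            "pseudo_reference=True to fall back to positive-sample geometric means"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        factors = np.exp(np.nanmedian(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class DispersionModel:
    """Per-sample size factors plus per-transcript dispersions.

    ``final`` = max(raw method-of-moments dispersion, fitted trend
    a0 + a1/mean), evaluated at each transcript's normalized base mean.
    """

    size_factors: pd.Series
    base_mean: pd.Series
    raw: pd.Series
    trend_coef: tuple[float, float]  # (a0, a1) of disp(mu) = a0 + a1/mu
    final: pd.Series


def fit_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: Sequence[Sequence[str]],
) -> DispersionModel:
    """Method-of-moments dispersions with a fitted 1/mean trend.

    ``groups`` lists the replicate sample-id sets over which within-group
    variability is pooled (each needs >= 2 members to contribute).  Raw
    dispersion of transcript i is (w_i - z_i)/mu_i^2 where w_i is the
    pooled within-group variance of normalized counts and z_i = mu_i *
    mean(1/s_j) removes the shot-noise component.  The trend
    disp(mu) = a0 + a1/mu is fitted by iteratively reweighted least squares
    over transcripts with positive raw dispersion; the working dispersion
    is max(raw, trend).
    """
    groups = [list(g) for g in groups]
    if all(len(g) < 2 for g in groups):
        raise ValueError("dispersion estimation requires replication in some group")
    q = counts.to_numpy(dtype=float) / sf.loc[counts.columns].to_numpy()[None, :]
    used_cols = [counts.columns.get_loc(s) for g in groups for s in g]
    mu = q[:, used_cols].mean(axis=1)

    ss = np.zeros(len(counts))
    dof = 0
    inv_s = []
    for g in groups:
        if len(g) < 2:
            continue
        cols = [counts.columns.get_loc(s) for s in g]
        sub = q[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dof += len(g) - 1
        inv_s.extend(1.0 / sf.loc[g].to_numpy())
    w = ss / dof
    z = mu * np.mean(inv_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.clip(np.where(mu > 0, (w - z) / mu**2, 0.0), 0.0, None)

    positive = (raw > 0) & (mu > 0)
    if positive.sum() >= 2:
        a0, a1 = _fit_trend(mu[positive], raw[positive])
    else:
        a0, a1 = max(float(np.nanmean(np.clip(raw, 0, None))), 1e-8), 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, a0)
    final = np.maximum(raw, np.clip(trend, 0.0, None))

    idx = counts.index
    return DispersionModel(
        size_factors=sf,
        base_mean=pd.Series(mu, index=idx, name="base_mean"),
        raw=pd.Series(raw, index=idx, name="dispersion_raw"),
        trend_coef=(float(a0), float(a1)),
        final=pd.Series(final, index=idx, name="dispersion"),
    )


def _fit_trend(mu: np.ndarray, disp: np.ndarray, n_iter: int = 8) -> tuple[float, float]:
    """Fit disp = a0 + a1/mu by gamma-style IRLS (weights 1/fitted^2)."""
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coef = np.array([np.median(disp), 0.0])
    for _ in range(n_iter):
        fitted = np.clip(X @ coef, 1e-8, None)
        w = 1.0 / fitted**2
        WX = X * w[:, None]
        coef_new, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * disp), rcond=None)
        if np.allclose(coef_new, coef, rtol=1e-6, atol=1e-10):
            coef = coef_new
            break
        coef = coef_new
    return float(max(coef[0], 0.0)), float(max(coef[1], 0.0))


# ---------------------------------------------------------------------------
# exact NB test
# ---------------------------------------------------------------------------


def _group_total_pmf(k: np.ndarray, mean: float, disp: float) -> np.ndarray:
    """pmf of a group's total count: NB with the group-sum dispersion, or
    Poisson in the disp -> 0 limit."""
    if disp < 1e-12:
        return poisson.pmf(k, mean)
    r = 1.0 / disp
    return nbinom.pmf(k, r, r / (r + mean))


def _exact_test_p(ka: int, kb: int, sa: float, sb: float, disp_a: float, disp_b: float) -> float:
    """Two-sided conditional exact test on the allocation of ka+kb reads."""
    ks = ka + kb
    if ks == 0:
        return 1.0
    mu = (ka + kb) / (sa + sb)
    a = np.arange(ks + 1)
    pa = _group_total_pmf(a, mu * sa, disp_a)
    pb = _group_total_pmf(a, mu * sb, disp_b)
    joint = pa * pb[::-1]
    total = joint.sum()
    if total <= 0:
        return 1.0
    observed = joint[ka]
    p = joint[joint <= observed * (1.0 + 1e-8)].sum() / total
    return float(min(max(p, 0.0), 1.0))


def nb_test(
    counts: pd.DataFrame,
    model: DispersionModel,
    comparison: ComparisonSpec,
    samples: pd.DataFrame,
) -> pd.Series:
    """Per-transcript two-sided exact NB p-values for one comparison.

    Conditions on the two groups' total count; group totals are NB with
    means proportional to summed size factors and a group-sum dispersion
    phi * sum(s_j^2) / (sum s_j)^2 derived from the transcript's final
    dispersion phi.
    """
    g1, g2 = comparison.sample_ids(samples)
    sf = model.size_factors
    sa, sb = float(sf.loc[g1].sum()), float(sf.loc[g2].sum())
    ra = float((sf.loc[g1] ** 2).sum()) / sa**2
    rb = float((sf.loc[g2] ** 2).sum()) / sb**2
    ka = counts[g1].sum(axis=1).to_numpy()
    kb = counts[g2].sum(axis=1).to_numpy()
    disp = model.final.loc[counts.index].to_numpy()
    p = np.empty(len(counts))
    for i in range(len(counts)):
        p[i] = _exact_test_p(
            int(ka[i]), int(kb[i]), sa, sb, disp[i] * ra, disp[i] * rb
        )
    return pd.Series(p, index=counts.index, name="p")


# ---------------------------------------------------------------------------
# fold change and significance
# ---------------------------------------------------------------------------


def efc(r1, r2):
    """Signed piecewise expression fold change (vectorized).

    ``sign(r2 - r1) * max/min`` when both values are positive, the raw
    difference ``r2 - r1`` when either is zero.  Positive values mean
    upregulation in sample/group 2.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if (r1 < 0).any() or (r2 < 0).any():
        raise ValueError("RPKM inputs must be nonnegative")
    lo = np.minimum(r1, r2)
    hi = np.maximum(r1, r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.sign(r2 - r1) * np.where(lo > 0, hi / lo, 0.0)
    out = np.where(lo > 0, ratio, r2 - r1)
    return out.item() if out.ndim == 0 else out


def call_significant(
    results: pd.DataFrame, q_cut: float = 0.05, log2_efc_cut: float = 2.0
) -> pd.DataFrame:
    """Flag transcripts with q < ``q_cut`` and log2|eFC| > ``log2_efc_cut``.

    The magnitude gate is applied to |eFC| (equivalently |eFC| > 4 at the
    default), so down-regulated transcripts are called symmetrically.
    """
    out = results.copy()
    magnitude = out["efc"].abs()
    with np.errstate(divide="ignore"):
        passes_fc = np.log2(np.where(magnitude > 0, magnitude, np.nan)) > log2_efc_cut
    out["is_sig"] = (out["q"] < q_cut) & np.nan_to_num(passes_fc, nan=False)
    return out


def run_comparison(
    data: AnnotatedCounts,
    expr: ExpressionMatrix,
    model: DispersionModel,
    comparison: ComparisonSpec,
    q_cut: float = 0.05,
    log2_efc_cut: float = 2.0,
) -> pd.DataFrame:
    """Full per-transcript DE table for one comparison.

    Columns: transcript_id, comparison, r1, r2 (group-mean RPKM, group 1 =
    first-named), efc, p, q (BH within this comparison), is_sig.
    """
    g1, g2 = comparison.sample_ids(data.samples)
    r1 = expr.rpkm[g1].mean(axis=1)
    r2 = expr.rpkm[g2].mean(axis=1)
    p = nb_test(data.counts, model, comparison, data.samples)
    result = pd.DataFrame(
        {
            "transcript_id": data.counts.index,
            "comparison": comparison.name,
            "r1": r1.to_numpy(),
            "r2": r2.to_numpy(),
            "efc": efc(r1.to_numpy(), r2.to_numpy()),
            "p": p.to_numpy(),
        }
    )
    result["q"] = bh_adjust(result["p"])
    return call_significant(result, q_cut=q_cut, log2_efc_cut=log2_efc_cut)


def enzyme_aggregate(
    results: pd.DataFrame,
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    comparison: ComparisonSpec,
    samples: pd.DataFrame,
    taxa: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Enzyme-level aggregation of a per-transcript DE table.

    Per EC: r1/r2 are the sums of member-transcript group-mean RPKM,
    enzyme eFC = efc(r1, r2), aeFC = eFC / n with n the number of member
    transcripts expressed (nonzero mean RPKM) in either group, and the
    enzyme is significant when any member transcript is.  Enzymes with
    n = 0 are omitted.

    Returns ``(enzymes, taxon_aefc)`` where ``taxon_aefc`` is an EC x taxon
    matrix of taxon-restricted aeFC (NaN where a taxon expresses no member).
    """
    g1, g2 = comparison.sample_ids(samples)
    r1 = expr.rpkm[g1].mean(axis=1)
    r2 = expr.rpkm[g2].mean(axis=1)
    sig = results.set_index("transcript_id")["is_sig"]

    members: dict[str, list[str]] = {}
    for tid, ecs in annotations["ec_numbers"].items():
        if tid not in expr.rpkm.index:
            continue
        for ec in ecs:
            members.setdefault(ec, []).append(tid)

    taxon_of = annotations["taxon"]
    rows = []
    taxon_rows: dict[str, dict[str, float]] = {}
    for ec in sorted(members):
        tids = members[ec]
        expressed = [t for t in tids if r1.loc[t] > 0 or r2.loc[t] > 0]
        n = len(expressed)
        if n == 0:
            continue
        e_r1, e_r2 = float(r1.loc[tids].sum()), float(r2.loc[tids].sum())
        e_efc = float(efc(e_r1, e_r2))
        rows.append(
            {
                "ec": ec,
                "comparison": comparison.name,
                "n": n,
                "r1": e_r1,
                "r2": e_r2,
                "efc": e_efc,
                "aefc": e_efc / n,
                "is_sig": bool(sig.loc[tids].any()),
            }
        )
        per_taxon: dict[str, float] = {}
        for taxon in taxa:
            t_tids = [t for t in tids if taxon_of.loc[t] == taxon]
            t_expr = [t for t in t_tids if r1.loc[t] > 0 or r2.loc[t] > 0]
            if not t_expr:
                per_taxon[taxon] = float("nan")
                continue
            t_r1, t_r2 = float(r1.loc[t_tids].sum()), float(r2.loc[t_tids].sum())
            per_taxon[taxon] = float(efc(t_r1, t_r2)) / len(t_expr)
        taxon_rows[ec] = per_taxon

    enzymes = pd.DataFrame(
        rows, columns=["ec", "comparison", "n", "r1", "r2", "efc", "aefc", "is_sig"]
    )
    taxon_aefc = pd.DataFrame.from_dict(taxon_rows, orient="index").rename_axis("ec")
    if len(taxon_aefc):
        taxon_aefc = taxon_aefc[list(taxa)] if list(taxa) else taxon_aefc
    return enzymes, taxon_aefc
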