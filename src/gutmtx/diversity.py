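"""Alpha/beta diversity indices and their group comparisons.

Per sample: observed richness S, Shannon entropy H = -sum p_i ln p_i,
Gini-Simpson 1 - sum p_i^2, Fisher's alpha (the root of
S = alpha * ln(1 + N/alpha)), Chao1 with a bootstrap standard deviation,
and the beta-diversity ratio |units in sample| / |units across all
samples|.  Group means +/- sd and Welch two-sample t tests between groups
mirror the study's biodiversity table.

"Species" defaults to the organism label carried by the transcript
annotation (finer than the 17 taxon bins) and falls back to the taxon bin
when no organism column is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import COMPARISONS, AnnotatedCounts
from .quantify import ExpressionMatrix

__all__ = [
    "alpha_indices",
    "fisher_alpha",
    "chao1",
    "beta_diversity",
    "compare_groups",
    "diversity_report",
]


@dataclass(frozen=True)
class AlphaIndices:
    richness: int
    shannon: float
    simpson: float
    fisher_alpha: float


def _clean(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("at least one positive abundance is required")
    return a


def fisher_alpha(S: int, N: float) -> float:
    """Solve S = alpha * ln(1 + N/alpha) for alpha by bracketed root-finding.

    Undefined (returns nan with a warning) when S <= 1 or S == N in count
    mode, where the log-series model degenerates.
    """
    if S <= 1:
        warnings.warn("Fisher's alpha is undefined for a single unit", stacklevel=2)
        return float("nan")

    def f(alpha: float) -> float:
        return alpha * np.log1p(N / alpha) - S

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            warnings.warn(
                "Fisher's alpha diverges (S too close to N)", stacklevel=2
            )
            return float("nan")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def alpha_indices(abundances: Sequence[float]) -> AlphaIndices:
    """Observed richness, Shannon (natural log), Gini-Simpson and Fisher's
    alpha for one sample's abundance vector (RPKM or counts)."""
    a = _clean(abundances)
    N = a.sum()
    p = a / N
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    S = int(a.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha = fisher_alpha(S, float(N))
    return AlphaIndices(S, shannon, simpson, alpha)


def chao1(
    counts: Sequence[int], bootstrap_reps: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Chao1 richness estimate with a bootstrap standard deviation.

    Classic estimator S + F1^2/(2 F2) when doubletons exist, bias-corrected
    S + F1(F1-1)/(2(F2+1)) when F2 = 0, where F1/F2 are singleton/doubleton
    counts.  The sd comes from ``bootstrap_reps`` multinomial resamples of
    the N observed individuals (fixed seed).
    """
    a = np.asarray(counts)
    if not np.issubdtype(a.dtype, np.integer):
        if not np.all(a == np.floor(a)):
            raise ValueError("Chao1 requires integer counts")
        a = a.astype(np.int64)
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("empty abundance vector")

    def estimate(v: np.ndarray) -> float:
        S = (v > 0).sum()
        F1 = (v == 1).sum()
        F2 = (v == 2).sum()
        if F2 > 0:
            return float(S + F1 * F1 / (2.0 * F2))
        return float(S + F1 * (F1 - 1) / 2.0)

    rng = np.random.default_rng(seed)
    N = int(a.sum())
    p = a / N
    boots = np.empty(bootstrap_reps)
    for i in range(bootstrap_reps):
        boots[i] = estimate(rng.multinomial(N, p))
    return estimate(a), float(boots.std(ddof=1))


def beta_diversity(sample_units: set, all_units: set) -> float:
    """Ratio of units observed in one sample to units observed anywhere."""
    if not all_units:
        raise ValueError("all_units must be nonempty")
    if not sample_units <= all_units:
        raise ValueError("sample_units must be a subset of all_units")
    return len(sample_units) / len(all_units)


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample two-sided t test; returns (t, df, p).

    Zero variance in both groups with equal means returns (0, df, 1) by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def _species_vectors(
    data: AnnotatedCounts, expr: ExpressionMatrix | None, level: str
) -> pd.DataFrame:
    """Per-sample abundance vectors aggregated to the species level.

    ``level='organism'`` uses the optional organism annotation column,
    falling back to taxon; ``level='taxon'`` forces the 17-bin level.
    Aggregates RPKM when ``expr`` is given, raw counts otherwise (the
    integer mode Chao1 needs).
    """
    if level == "organism" and "organism" in data.annotations.columns:
        labels = data.annotations["organism"]
    else:
        labels = data.annotations["taxon"]
    matrix = expr.rpkm if expr is not None else data.counts
    return matrix.groupby(labels.loc[matrix.index].to_numpy()).sum()


def diversity_report(
    data: AnnotatedCounts,
    expr: ExpressionMatrix | None = None,
    level: str = "organism",
    bootstrap_reps: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level diversity summary and pairwise group t tests.

    Returns ``(summary, tests)``: ``summary`` has one row per genotype/diet
    group and ``mean``/``sd`` columns per index (richness, chao1,
    fisher_alpha, shannon, simpson, beta); ``tests`` has one Welch t test
    per index for each of the four pairwise comparisons.

    Chao1 always uses raw integer counts; the other indices use RPKM when
    ``expr`` is provided.
    """
    by_species_counts = _species_vectors(data, None, level)
    by_species = _species_vectors(data, expr, level) if expr is not None else by_species_counts
    all_units = set(by_species.index[(by_species > 0).any(axis=1)])

    rows = []
    for sample in data.counts.columns:
        v = by_species[sample]
        idx = alpha_indices(v[v > 0])
        est, sd = chao1(
            by_species_counts[sample][by_species_counts[sample] > 0].to_numpy(),
            bootstrap_reps=bootstrap_reps,
            seed=seed,
        )
        rows.append(
            {
                "sample_id": sample,
                "group": data.group_of(sample),
                "richness": idx.richness,
                "chao1": est,
                "chao1_sd": sd,
                "fisher_alpha": idx.fisher_alpha,
                "shannon": idx.shannon,
                "simpson": idx.simpson,
                "beta": beta_diversity(set(v.index[v > 0]), all_units),
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample_id")

    indices = ["richness", "chao1", "fisher_alpha", "shannon", "simpson", "beta"]
    summary = per_sample.groupby("group")[indices].agg(["mean", "std"])

    test_rows = []
    for name, spec in COMPARISONS.items():
        g1, g2 = spec.sample_ids(data.samples)
        for index in indices:
            t, df, p = compare_groups(
                per_sample.loc[g1, index], per_sample.loc[g2, index]
            )
            test_rows.append(
                {"comparison": name, "index": index, "t": t, "df": df, "p": p}
            )
    return summary, pd.DataFrame(test_rows)
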