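"""Ordination and permutational multivariate analysis of variance.

PERMANOVA computes Anderson's pseudo-F from the Gower-centered squared
distance matrix; p-values come from unrestricted permutation of the raw
observations (sample labels), with the floor 1/(n_perm + 1), and q-values
from Benjamini-Hochberg adjustment across the family of tests run
together.  The two-factor crossed case (genotype, diet) partitions the
centered matrix with the additive model's projections.  PCA operates on
log10(x + 1)-transformed, feature-centered data via the singular value
decomposition, with component signs fixed by making each component's
largest-magnitude loading positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .data_model import COMPARISONS, ComparisonSpec
from .pathways import bh_adjust

__all__ = [
    "distance",
    "permanova",
    "pca",
    "PcaResult",
    "pc_separation_test",
]


def distance(matrix: pd.DataFrame, metric: str = "bray-curtis") -> DistanceMatrix:
    """Sample x sample distance matrix from a sample x feature table.

    ``bray-curtis`` (sum |x-y| / sum (x+y); requires nonnegative features)
    or ``euclidean``.  A pair of all-zero samples has undefined
    Bray-Curtis distance and is reported as 0 with a warning.
    """
    X = matrix.to_numpy(dtype=float)
    if metric in ("bray-curtis", "braycurtis"):
        if (X < 0).any():
            raise ValueError("bray-curtis requires nonnegative features")
        with np.errstate(invalid="ignore"):
            d = pdist(X, metric="braycurtis")
        if np.isnan(d).any():
            warnings.warn(
                "all-zero sample pair under bray-curtis; distance set to 0",
                stacklevel=2,
            )
            d = np.nan_to_num(d, nan=0.0)
    elif metric == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in matrix.index])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    return c @ a @ c


def _hat(design: np.ndarray) -> np.ndarray:
    return design @ np.linalg.pinv(design)


def _dummy(labels: np.ndarray) -> np.ndarray:
    levels = sorted(set(labels))
    return np.column_stack([(labels == lv).astype(float) for lv in levels])


def _factor_f_stats(
    G: np.ndarray, factors: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-F per factor under the (additive, for two factors) model.

    Returns (F values, degenerate flags).  SS_f is the trace of the
    difference between the full-model and the f-omitted-model projections
    applied to G; the residual comes from the full additive model.
    """
    n = G.shape[0]
    ones = np.ones((n, 1))
    designs = {name: _dummy(lab) for name, lab in factors.items()}
    full = _hat(np.column_stack([ones] + list(designs.values())))
    df_res = n - 1 - sum(d.shape[1] - 1 for d in designs.values())
    ss_tot = float(np.trace(G))
    eps = 1e-10 * max(abs(ss_tot), 1.0)  # guards exact-fit round-off
    ss_res = float(np.trace((np.eye(n) - full) @ G))
    Fs, degenerate = [], []
    for name in factors:
        others = [d for other, d in designs.items() if other != name]
        reduced = _hat(np.column_stack([ones] + others))
        df_f = designs[name].shape[1] - 1
        ss_f = float(np.trace((full - reduced) @ G))
        if ss_res <= eps:
            degenerate.append(ss_f <= eps)
            Fs.append(np.nan if ss_f <= eps else np.inf)
        else:
            degenerate.append(False)
            Fs.append((ss_f / df_f) / (ss_res / df_res))
    return np.asarray(Fs), np.asarray(degenerate)


def permanova(
    d: DistanceMatrix,
    factors: Mapping[str, Sequence],
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """One- or two-way PERMANOVA with permutation p-values.

    ``factors`` maps factor name -> per-sample labels (in the distance
    matrix's id order).  For two crossed factors, main effects are tested
    against the additive-model residual under unrestricted permutation of
    raw observations.  p = (#{F_perm >= F_obs} + 1) / (n_perm + 1); BH
    q-values are computed across the factors tested together.
    """
    labels = {name: np.asarray(lab) for name, lab in factors.items()}
    if not labels:
        raise ValueError("at least one factor is required")
    for name, lab in labels.items():
        counts = pd.Series(lab).value_counts()
        if len(counts) < 2:
            raise ValueError(f"factor {name!r} has a single level")
        if (counts < 2).any():
            raise ValueError(f"factor {name!r} has a level with < 2 samples")
    dist = np.asarray(d.data, dtype=float)
    G = _gower_center(dist)
    f_obs, degenerate = _factor_f_stats(G, labels)

    rng = np.random.default_rng(seed)
    n = dist.shape[0]
    exceed = np.zeros(len(labels))
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            f_perm, _ = _factor_f_stats(Gp, labels)
            exceed += f_perm >= f_obs
    p = (exceed + 1.0) / (n_perm + 1.0)
    p = np.where(degenerate, 1.0, p)  # permutation-invariant (all-equal) data
    result = pd.DataFrame(
        {
            "factor": list(labels),
            "pseudo_F": f_obs,
            "p": p,
            "n_permutations": n_perm,
            "seed": seed,
        }
    )
    result["q"] = bh_adjust(result["p"])
    return result


@dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # feature x component
    variance_fraction: pd.Series


def pca(matrix: pd.DataFrame, transform: str | None = "log10") -> PcaResult:
    """PCA of a sample x feature table via SVD.

    ``transform='log10'`` applies log10(x + 1) elementwise first (the
    default for abundance-like data); features are then centered.  Signs
    are deterministic: each component's largest-magnitude loading is made
    positive.
    """
    X = matrix.to_numpy(dtype=float)
    if transform == "log10":
        if (X < 0).any():
            raise ValueError("log10(x+1) transform requires nonnegative data")
        X = np.log10(X + 1.0)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    X = X - X.mean(axis=0, keepdims=True)
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1, X.shape[1]) or 1
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # fix signs: largest-|loading| positive per component
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2
    total = var.sum()
    if total <= 0:
        warnings.warn("constant matrix: zero variance explained", stacklevel=2)
        fractions = np.zeros(k)
    else:
        fractions = var / total
    comps = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=matrix.index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=comps),
        variance_fraction=pd.Series(fractions, index=comps, name="variance_fraction"),
    )


def pc_separation_test(
    result: PcaResult,
    samples: pd.DataFrame,
    comparisons: Mapping[str, ComparisonSpec] = COMPARISONS,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """How well PC1/PC2 separate the sample types.

    Runs a one-way euclidean PERMANOVA on the first two components' scores
    for each pairwise group comparison, then BH-adjusts across the family.
    """
    if result.scores.shape[1] < 2:
        raise ValueError("need at least two components")
    rows = []
    for name, spec in comparisons.items():
        g1, g2 = spec.sample_ids(samples)
        ids = g1 + g2
        scores = result.scores.loc[ids, ["PC1", "PC2"]]
        d = distance(scores, metric="euclidean")
        labels = ["g1"] * len(g1) + ["g2"] * len(g2)
        res = permanova(d, {"group": labels}, n_perm=n_perm, seed=seed)
        rows.append(
            {
                "comparison": name,
                "pseudo_F": float(res["pseudo_F"].iloc[0]),
                "p": float(res["p"].iloc[0]),
                "n_permutations": n_perm,
                "seed": seed,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out
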