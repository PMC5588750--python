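"""Low-expression filtering, RPKM normalization, taxon aggregation,
presence-tier Venn partitioning and rarefaction.

RPKM (reads per kilobase of transcript per million mapped reads) is the
expression currency of the whole pipeline:

    rpkm = count / ((length_bp / 1e3) * (total_mapped_reads / 1e6))

with zero counts mapping exactly to zero.  The per-sample denominator is
the number of reads mapped to *retained* transcripts, recomputed after the
low-expression filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnnotatedCounts, UNASSIGNED

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "PresencePartition",
    "filter_low_expression",
    "rpkm",
    "taxon_abundance",
    "presence_partition",
    "rarefaction_curve",
]


@dataclass
class FilterReport:
    min_reads: int
    n_removed: int
    n_retained: int
    removed_reads_fraction: float  # fraction of all mapped reads carried by removed transcripts
    per_sample: bool = False


@dataclass
class ExpressionMatrix:
    """RPKM expression with the provenance needed to reproduce it."""

    rpkm: pd.DataFrame  # transcript x sample, nonnegative reals
    totals: pd.Series  # per-sample denominator (mapped reads)
    min_reads: int | None = None  # filter threshold applied upstream, if any


@dataclass
class PresencePartition:
    """Venn partition of transcripts over the four genotype/diet groups.

    A transcript is present in a group when its mean RPKM over the group's
    replicates passes the threshold (strictly > 0 at the lowest tier,
    >= otherwise).  ``region_counts`` maps each of the 15 nonempty group
    combinations (a sorted tuple of group names) to its exclusive count.
    """

    threshold: float
    presence: dict[str, set[str]]  # group -> transcripts present
    region_counts: dict[tuple[str, ...], int]

    @property
    def n_present(self) -> int:
        return sum(self.region_counts.values())


def filter_low_expression(
    data: AnnotatedCounts, min_reads: int = 5, per_sample: bool = False
) -> tuple[AnnotatedCounts, FilterReport]:
    """Drop transcripts expressed at low levels.

    By default a transcript is removed when its total mapped reads across
    all samples is < ``min_reads`` (strict).  With ``per_sample=True`` the
    rule is applied to each sample's count and a transcript is removed when
    every sample falls below the threshold.  Per-sample totals of the
    returned dataset are recomputed from the retained transcripts.
    """
    if per_sample:
        keep = (data.counts >= min_reads).any(axis=1)
    else:
        keep = data.counts.sum(axis=1) >= min_reads
    if not keep.any():
        raise ValueError(
            f"all {data.n_transcripts} transcripts fall below min_reads={min_reads}; "
            "review the threshold"
        )
    total_reads = int(data.counts.to_numpy().sum())
    removed_reads = int(data.counts.loc[~keep].to_numpy().sum())
    filtered = data.subset_transcripts(list(data.counts.index[keep]))
    report = FilterReport(
        min_reads=min_reads,
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        removed_reads_fraction=removed_reads / total_reads if total_reads else 0.0,
        per_sample=per_sample,
    )
    return filtered, report


def rpkm(data: AnnotatedCounts) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads."""
    totals = data.samples["total_mapped_reads"].astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero mapped reads")
    lengths_kb = data.annotations["length_bp"].to_numpy(dtype=float) / 1e3
    denom = lengths_kb[:, None] * (totals.to_numpy() / 1e6)[None, :]
    values = data.counts.to_numpy(dtype=float) / denom
    matrix = pd.DataFrame(values, index=data.counts.index, columns=data.counts.columns)
    return ExpressionMatrix(rpkm=matrix, totals=totals, min_reads=None)


def taxon_abundance(
    expr: ExpressionMatrix, annotations: pd.DataFrame, taxa: Sequence[str]
) -> pd.DataFrame:
    """Taxon x sample abundance: sum of member transcripts' RPKM.

    Every configured taxon appears (zero row if no member transcript);
    ``unassigned`` appears last when any transcript carries it.
    """
    groups = expr.rpkm.groupby(annotations.loc[expr.rpkm.index, "taxon"].to_numpy()).sum()
    order = [t for t in taxa] + (
        [UNASSIGNED] if UNASSIGNED in groups.index else []
    )
    return groups.reindex(order, fill_value=0.0).rename_axis("taxon")


def presence_partition(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    thresholds: Sequence[float] = (0.0, 10.0, 100.0),
) -> dict[float, PresencePartition]:
    """Venn partition of transcripts per RPKM tier.

    Presence of a transcript in a genotype/diet group is decided on the
    group mean RPKM over its replicates: strictly positive for threshold 0,
    ``mean >= threshold`` otherwise.  Returns one partition per tier with
    all 15 nonempty-region counts.
    """
    group_labels = samples["genotype"].str.cat(samples["diet"], sep="-")
    group_means = expr.rpkm.T.groupby(group_labels).mean().T  # transcript x group
    group_names = sorted(group_means.columns)
    out: dict[float, PresencePartition] = {}
    for threshold in thresholds:
        if threshold == 0:
            present = group_means > 0
        else:
            present = group_means >= threshold
        presence = {
            g: set(present.index[present[g]]) for g in group_names
        }
        membership = present[group_names].to_numpy()
        region_counts: dict[tuple[str, ...], int] = {}
        anywhere = membership.any(axis=1)
        patterns, counts = np.unique(membership[anywhere], axis=0, return_counts=True)
        for pattern, count in zip(patterns, counts):
            key = tuple(g for g, m in zip(group_names, pattern) if m)
            region_counts[key] = int(count)
        out[threshold] = PresencePartition(threshold, presence, region_counts)
    return out


def rarefaction_curve(
    data: AnnotatedCounts,
    depths: Sequence[int],
    reps: int = 50,
    seed: int = 0,
    unit: str = "transcript",
) -> pd.DataFrame:
    """Mean distinct-unit count in without-replacement subsamples of reads.

    For each sample and each depth, reads (expanded from the count vector)
    are subsampled uniformly without replacement ``reps`` times and the
    mean number of distinct units (transcripts, or enzymes via the EC
    annotation) is recorded.  Returns a depth x sample table.
    """
    if unit not in ("transcript", "enzyme"):
        raise ValueError("unit must be 'transcript' or 'enzyme'")
    depths = sorted(int(d) for d in depths)
    rng = np.random.default_rng(seed)
    result = pd.DataFrame(index=pd.Index(depths, name="depth"), columns=data.counts.columns, dtype=float)
    if unit == "enzyme":
        ec_sets = data.annotations["ec_numbers"]
    for sample in data.counts.columns:
        counts = data.counts[sample].to_numpy()
        total = int(counts.sum())
        for depth in depths:
            if depth > total:
                raise ValueError(
                    f"depth {depth} exceeds sample {sample!r} total {total}"
                )
            if depth == 0:
                result.loc[depth, sample] = 0.0
                continue
            if depth == total:
                drawn_any = counts > 0
                if unit == "transcript":
                    result.loc[depth, sample] = float(drawn_any.sum())
                else:
                    result.loc[depth, sample] = float(
                        len(set().union(*ec_sets[drawn_any], frozenset()))
                    )
                continue
            values = np.empty(reps)
            for rep in range(reps):
                draw = rng.multivariate_hypergeometric(counts, depth)
                hit = draw > 0
                if unit == "transcript":
                    values[rep] = hit.sum()
                else:
                    values[rep] = len(set().union(*ec_sets[hit], frozenset()))
            result.loc[depth, sample] = float(values.mean())
    return result
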