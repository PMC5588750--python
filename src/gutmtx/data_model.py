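"""Core domain types and tabular I/O for annotated metatranscriptome count data.

The pipeline's sole required input is an :class:`AnnotatedCounts`: a
transcript x sample matrix of raw mapped-read counts joined to per-transcript
annotations (taxon bin, EC numbers, length) and per-sample metadata
(genotype, diet, replicate).  Everything downstream — RPKM, diversity,
differential expression, enrichment, ordination — consumes this object.

All tables are one-record-per-row TSV with a header; sample order is the
order of the samples file, so writes are byte-reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TAXA",
    "UNASSIGNED",
    "GENOTYPES",
    "DIETS",
    "ValidationError",
    "ComparisonSpec",
    "COMPARISONS",
    "AnnotatedCounts",
    "load_dataset",
    "write_table",
    "read_table",
]

#: The 17 family/class-level bins into which every transcript's taxonomic
#: assignment is collapsed.  This list is configuration, not a code constant:
#: any 17-label list may be supplied to the validators instead.
DEFAULT_TAXA: tuple[str, ...] = (
    "Lachnospiraceae",
    "Clostridiaceae",
    "Ruminococcaceae",
    "Eubacteriaceae",
    "Oscillospiraceae",
    "other Firmicutes",
    "other Clostridia",
    "Bacilli",
    "Bacteroidaceae",
    "Porphyromonadaceae",
    "Rikenellaceae",
    "other Bacteroidales",
    "Deltaproteobacteria",
    "other Proteobacteria",
    "Actinobacteria",
    "Verrucomicrobia",
    "other bacteria",
)

#: Catch-all label for transcripts outside the 17 bins.
UNASSIGNED = "unassigned"

GENOTYPES = ("WT", "Plin2")
DIETS = ("HF", "LF")

#: 4-field Enzyme Commission identifier, e.g. ``2.7.1.1``.
EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.\d+$")


class ValidationError(ValueError):
    """Raised when an input table violates a dataset invariant."""


@dataclass(frozen=True)
class ComparisonSpec:
    """One of the four pairwise genotype/diet comparisons.

    ``group1`` is the first-named group of the comparison (sample 1 of the
    fold-change statistic) and ``group2`` the second; each is a
    ``(genotype, diet)`` pair.  A positive eFC means upregulation in
    ``group2``.
    """

    name: str
    group1: tuple[str, str]
    group2: tuple[str, str]

    def __post_init__(self) -> None:
        if self.group1 == self.group2:
            raise ValidationError("comparison groups must be disjoint")

    def sample_ids(self, samples: pd.DataFrame) -> tuple[list[str], list[str]]:
        """Return (group1 ids, group2 ids) from a samples table."""
        ids = []
        for genotype, diet in (self.group1, self.group2):
            mask = (samples["genotype"] == genotype) & (samples["diet"] == diet)
            sel = list(samples.index[mask])
            if not sel:
                raise ValidationError(
                    f"comparison {self.name}: no samples for {genotype}-{diet}"
                )
            ids.append(sel)
        return ids[0], ids[1]


#: The four comparisons explored in the study design.  First-named group
#: first: e.g. Geno-HF is Plin2-HF (group 1) vs. WT-HF (group 2).
COMPARISONS: dict[str, ComparisonSpec] = {
    "Geno-HF": ComparisonSpec("Geno-HF", ("Plin2", "HF"), ("WT", "HF")),
    "Geno-LF": ComparisonSpec("Geno-LF", ("Plin2", "LF"), ("WT", "LF")),
    "Diet-Plin2": ComparisonSpec("Diet-Plin2", ("Plin2", "HF"), ("Plin2", "LF")),
    "Diet-WT": ComparisonSpec("Diet-WT", ("WT", "HF"), ("WT", "LF")),
}


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise ValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class AnnotatedCounts:
    """Raw transcript counts joined to annotations and sample metadata.

    Attributes
    ----------
    counts : DataFrame
        transcript x sample matrix of nonnegative integer mapped-read counts;
        index = transcript ids, columns = sample ids.
    annotations : DataFrame
        indexed by transcript id, columns ``taxon``, ``ec_numbers`` (frozenset
        of EC strings), ``length_bp`` and optionally ``organism`` (a finer
        species-level label used for diversity; falls back to ``taxon``).
    samples : DataFrame
        indexed by sample id, columns ``genotype``, ``diet``, ``replicate``,
        ``total_mapped_reads``.
    taxa : tuple of str
        the configured 17 taxon bins (plus implicit ``unassigned``).
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame
    samples: pd.DataFrame
    taxa: tuple[str, ...] = DEFAULT_TAXA

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if len(self.taxa) != 17:
            raise ValidationError(
                f"expected exactly 17 taxon bins, got {len(self.taxa)}"
            )
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.counts.index, "transcript_id")
        _check_unique(self.counts.columns, "sample_id")
        if set(self.counts.index) != set(self.annotations.index):
            offending = set(self.counts.index) ^ set(self.annotations.index)
            raise ValidationError(
                f"counts/annotations transcript ids disagree, e.g. "
                f"{sorted(offending)[0]!r}"
            )
        if set(self.counts.columns) != set(self.samples.index):
            offending = set(self.counts.columns) ^ set(self.samples.index)
            raise ValidationError(
                f"counts/samples sample ids disagree, e.g. {sorted(offending)[0]!r}"
            )
        # align annotation rows to count rows, samples to columns
        self.annotations = self.annotations.loc[self.counts.index]
        self.samples = self.samples.loc[self.counts.columns]

        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                bad = np.argwhere(arr != np.floor(arr))[0]
                raise ValidationError(
                    f"non-integer count at transcript {self.counts.index[bad[0]]!r},"
                    f" sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at transcript {self.counts.index[bad[0]]!r},"
                f" sample {self.counts.columns[bad[1]]!r}"
            )

        allowed = set(self.taxa) | {UNASSIGNED}
        bad_taxa = set(self.annotations["taxon"]) - allowed
        if bad_taxa:
            raise ValidationError(
                f"unknown taxon label(s) {sorted(bad_taxa)}; allowed labels are "
                f"{sorted(allowed)}"
            )
        if (self.annotations["length_bp"] < 1).any():
            tid = self.annotations.index[self.annotations["length_bp"] < 1][0]
            raise ValidationError(f"transcript {tid!r} has length_bp < 1")
        for tid, ecs in self.annotations["ec_numbers"].items():
            for ec in ecs:
                if not EC_PATTERN.match(ec):
                    raise ValidationError(
                        f"transcript {tid!r}: malformed EC number {ec!r}"
                    )

        for col in ("genotype", "diet"):
            allowed_vals = GENOTYPES if col == "genotype" else DIETS
            bad = set(self.samples[col]) - set(allowed_vals)
            if bad:
                raise ValidationError(
                    f"unknown {col} value(s) {sorted(bad)}; allowed: {allowed_vals}"
                )
        combos = list(
            zip(self.samples["genotype"], self.samples["diet"], self.samples["replicate"])
        )
        _check_unique((f"{g}-{d}-r{r}" for g, d, r in combos), "(genotype, diet, replicate)")

        if "total_mapped_reads" not in self.samples.columns:
            self.samples = self.samples.assign(
                total_mapped_reads=self.counts.sum(axis=0).to_numpy()
            )
        totals = self.samples["total_mapped_reads"]
        if self.counts.shape[0] and (totals <= 0).any():
            sid = totals.index[totals <= 0][0]
            raise ValidationError(f"sample {sid!r} has total_mapped_reads <= 0")

    # -- convenience -----------------------------------------------------
    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_of(self, sample_id: str) -> str:
        row = self.samples.loc[sample_id]
        return f"{row['genotype']}-{row['diet']}"

    @property
    def group_labels(self) -> pd.Series:
        """Genotype-diet group per sample, e.g. ``Plin2-HF``."""
        return self.samples["genotype"].str.cat(self.samples["diet"], sep="-")

    def subset_transcripts(self, transcript_ids: Sequence[str]) -> "AnnotatedCounts":
        """Restricted copy; per-sample totals are recomputed from the kept rows."""
        counts = self.counts.loc[list(transcript_ids)]
        samples = self.samples.drop(columns=["total_mapped_reads"])
        return AnnotatedCounts(
            counts=counts.copy(),
            annotations=self.annotations.loc[list(transcript_ids)].copy(),
            samples=samples.copy(),
            taxa=self.taxa,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

#: TSV float format: 12 significant digits so round-trips agree to <1e-9 rel.
FLOAT_FORMAT = "%.12g"


def _parse_ec_field(value: object) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    return frozenset(str(value).split(";"))


def _format_ec_field(ecs: frozenset[str]) -> str:
    return ";".join(sorted(ecs))


def load_dataset(
    counts_path: str | Path,
    annotations_path: str | Path,
    samples_path: str | Path,
    taxa: Sequence[str] = DEFAULT_TAXA,
) -> AnnotatedCounts:
    """Read the three input TSVs and return a validated :class:`AnnotatedCounts`.

    ``counts.tsv`` has a ``transcript_id`` column followed by one integer
    column per sample; ``annotations.tsv`` has ``transcript_id``, ``taxon``,
    ``ec_numbers`` (semicolon-separated, possibly empty), ``length_bp`` and
    optionally ``organism``; ``samples.tsv`` has ``sample_id``, ``genotype``,
    ``diet``, ``replicate`` and optionally ``total_mapped_reads`` (computed
    from the column sums when absent).
    """
    counts = pd.read_csv(counts_path, sep="\t", dtype={"transcript_id": str})
    if "transcript_id" not in counts.columns:
        raise ValidationError(f"{counts_path}: missing 'transcript_id' column")
    counts = counts.set_index("transcript_id")

    annotations = pd.read_csv(
        annotations_path, sep="\t", dtype={"transcript_id": str, "taxon": str}
    )
    required = {"transcript_id", "taxon", "ec_numbers", "length_bp"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValidationError(f"{annotations_path}: missing columns {sorted(missing)}")
    annotations = annotations.set_index("transcript_id")
    annotations["ec_numbers"] = annotations["ec_numbers"].map(_parse_ec_field)

    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "genotype", "diet", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValidationError(f"{samples_path}: missing columns {sorted(missing)}")
    samples = samples.set_index("sample_id")

    # preserve the samples-file ordering for the count columns
    counts = counts[list(samples.index)] if set(counts.columns) == set(samples.index) else counts
    return AnnotatedCounts(counts=counts, annotations=annotations, samples=samples, taxa=taxa)


def save_dataset(data: AnnotatedCounts, outdir: str | Path) -> dict[str, Path]:
    """Write counts/annotations/samples TSVs; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "annotations": outdir / "annotations.tsv",
        "samples": outdir / "samples.tsv",
    }
    data.counts.rename_axis("transcript_id").reset_index().to_csv(
        paths["counts"], sep="\t", index=False
    )
    annot = data.annotations.copy()
    annot["ec_numbers"] = annot["ec_numbers"].map(_format_ec_field)
    annot.rename_axis("transcript_id").reset_index().to_csv(
        paths["annotations"], sep="\t", index=False
    )
    data.samples.rename_axis("sample_id").reset_index().to_csv(
        paths["samples"], sep="\t", index=False
    )
    return paths


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with a fixed column order.

    Floats are serialized with 12 significant digits, so reading the file
    back reproduces the records to better than 1e-9 relative error.
    """
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
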