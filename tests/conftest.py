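"""Shared fixtures: hand-built tiny datasets and one session-scoped
synthetic dataset reused by the slower statistical tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gutmtx.data_model import DEFAULT_TAXA, AnnotatedCounts
from gutmtx.synthetic import SynthConfig, generate_dataset


def make_dataset(
    counts: np.ndarray,
    lengths=None,
    taxa=None,
    ecs=None,
    totals=None,
    n_groups: int = 4,
) -> AnnotatedCounts:
    """Hand-rolled AnnotatedCounts; one replicate per group by default."""
    counts = np.asarray(counts)
    n_t, n_s = counts.shape
    groups = [("Plin2", "HF"), ("WT", "HF"), ("Plin2", "LF"), ("WT", "LF")]
    block = max(n_s // n_groups, 1)
    sample_rows = []
    rep = {}
    for j in range(n_s):
        g, d = groups[min(j // block, n_groups - 1)]
        rep[(g, d)] = rep.get((g, d), 0) + 1
        sample_rows.append((f"{g}-{d}-{rep[(g, d)]}", g, d, rep[(g, d)]))
    samples = pd.DataFrame(
        {
            "genotype": [g for _, g, _, _ in sample_rows],
            "diet": [d for _, _, d, _ in sample_rows],
            "replicate": [r for _, _, _, r in sample_rows],
        },
        index=pd.Index([s for s, *_ in sample_rows], name="sample_id"),
    )
    if totals is not None:
        samples["total_mapped_reads"] = totals
    tids = [f"T{i}" for i in range(n_t)]
    annotations = pd.DataFrame(
        {
            "taxon": taxa if taxa is not None else [DEFAULT_TAXA[0]] * n_t,
            "ec_numbers": ecs if ecs is not None else [frozenset()] * n_t,
            "length_bp": lengths if lengths is not None else [1000] * n_t,
        },
        index=pd.Index(tids, name="transcript_id"),
    )
    return AnnotatedCounts(
        counts=pd.DataFrame(counts, index=tids, columns=samples.index),
        annotations=annotations,
        samples=samples,
    )


@pytest.fixture(scope="session")
def synth_default():
    """Moderate synthetic dataset with planted effects (seed frozen)."""
    config = SynthConfig(n_transcripts=800, seed=42)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def synth_null():
    """Fully null synthetic dataset (no differential transcripts)."""
    config = SynthConfig(n_transcripts=1000, pi_de=0.0, seed=7)
    return generate_dataset(config)
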