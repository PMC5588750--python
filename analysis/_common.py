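"""Shared paths and loading for the numbered analysis scripts.

Run the scripts in order from the repository root; each one reads the
synthetic dataset written by ``01_simulate.py`` under ``results/data`` and
writes its own tables under ``results/``.
"""

from pathlib import Path

from gutmtx.data_model import load_dataset
from gutmtx.pathways import build_pathway_graph

RESULTS = Path("results")
DATA = RESULTS / "data"
SEED = 20260927  # one frozen seed for the whole analysis


def load_data():
    return load_dataset(
        DATA / "counts.tsv", DATA / "annotations.tsv", DATA / "samples.tsv"
    )


def load_pathway():
    return build_pathway_graph(DATA / "pathway.kgml")
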