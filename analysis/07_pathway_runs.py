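"""Coordinated consecutive-enzyme runs along the pathway graph.

For each comparison, maps significant enzymes' aeFC values onto the
pathway graph and reports every maximal directed path whose enzymes all
shift in the same direction (length >= 3) — the formal counterpart of
coordinated upregulation of consecutive metabolic enzymes.  Also writes
per-taxon up/down tallies along each run and Cytoscape-ready exports.
"""

import pandas as pd

from _common import RESULTS, load_data, load_pathway

from gutmtx import pathways as pw
from gutmtx import quantify as qt
from gutmtx.data_model import COMPARISONS, read_table, write_table


def main() -> None:
    pathway = load_pathway()
    data = load_data()
    filtered, _ = qt.filter_low_expression(data)
    for name in COMPARISONS:
        enz = read_table(RESULTS / f"enzymes_{name}.tsv")
        values = dict(zip(enz.loc[enz["is_sig"], "ec"], enz.loc[enz["is_sig"], "aefc"]))
        runs = pw.find_coordinated_runs(pathway, values, min_len=3, comparison=name)
        rows = [
            {
                "comparison": r.comparison,
                "direction": r.direction,
                "length": r.length,
                "mean_abs_aefc": r.mean_abs_aefc,
                "ecs": ">".join(r.ecs),
            }
            for r in runs
        ]
        write_table(
            pd.DataFrame(rows, columns=["comparison", "direction", "length", "mean_abs_aefc", "ecs"]),
            RESULTS / f"runs_{name}.tsv",
        )
        pw.export_cytoscape(
            pathway,
            dict(zip(enz["ec"], enz["aefc"])),
            set(enz.loc[enz["is_sig"], "ec"]),
            RESULTS / f"pathway_{name}",
        )
        print(f"{name}: {len(runs)} coordinated runs")
        taxon_aefc = read_table(RESULTS / f"enzymes_taxon_aefc_{name}.tsv").set_index("ec")
        for r in runs:
            tally = pw.taxon_direction_tally(list(r.ecs), taxon_aefc)
            consistent = tally[(tally["n_up"] >= r.length / 2) | (tally["n_down"] >= r.length / 2)]
            print(
                f"  {r.direction} run {'>'.join(r.ecs)} "
                f"(mean |aeFC| {r.mean_abs_aefc:.1f}); "
                f"{len(consistent)} taxa shift >= half the enzymes one way"
            )
            write_table(
                tally.reset_index(),
                RESULTS / f"run_taxa_{name}_{r.ecs[0].replace('.', '-')}.tsv",
            )


if __name__ == "__main__":
    main()
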