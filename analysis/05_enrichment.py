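"""Hypergeometric enrichment of significant transcripts in taxa and of
significant enzymes in pathways.

The taxon universe is every transcript observed in >= 1 sample; the
pathway universe is every EC expressed in >= 1 sample; sets with fewer
than two members are excluded; BH FDR at 0.05.
"""

import networkx as nx
import pandas as pd

from _common import RESULTS, load_data, load_pathway

from gutmtx import pathways as pw
from gutmtx import quantify as qt
from gutmtx.data_model import COMPARISONS, read_table, write_table


def main() -> None:
    data = load_data()
    filtered, _ = qt.filter_low_expression(data)
    expr = qt.rpkm(filtered)
    universe = set(expr.rpkm.index[(expr.rpkm > 0).any(axis=1)])
    taxon_sets = {
        t: set(filtered.annotations.index[filtered.annotations["taxon"] == t])
        for t in filtered.taxa
    }
    pathway = load_pathway()
    chains = {
        f"chain.{i + 1}": set(c)
        for i, c in enumerate(sorted(map(sorted, nx.weakly_connected_components(pathway))))
    }
    for name in COMPARISONS:
        de = read_table(RESULTS / f"de_{name}.tsv")
        sig = set(de.loc[de["is_sig"], "transcript_id"]) & universe
        taxa = pw.hypergeom_enrich(taxon_sets, universe, sig)
        write_table(taxa, RESULTS / f"enrichment_taxa_{name}.tsv")
        enz = read_table(RESULTS / f"enzymes_{name}.tsv")
        ec_universe = set(enz["ec"])
        sig_ecs = set(enz.loc[enz["is_sig"], "ec"])
        paths = pw.hypergeom_enrich(chains, ec_universe, sig_ecs)
        write_table(paths, RESULTS / f"enrichment_pathways_{name}.tsv")
        print(
            f"{name}: {int((taxa['q'] < 0.05).sum())}/{len(taxa)} taxa and "
            f"{int((paths['q'] < 0.05).sum())}/{len(paths)} pathways enriched "
            f"(n={len(sig)} sig transcripts, {len(sig_ecs)} sig enzymes)"
        )


if __name__ == "__main__":
    main()
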