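"""PERMANOVA and PCA of the community expression profiles.

Two-way (genotype x diet) PERMANOVA on Bray-Curtis distances of taxon
abundance, univariate euclidean PERMANOVA per taxon, PCA of the
log10(x+1) expression matrix, and PERMANOVA of PC1/PC2 separation for
each pairwise group comparison (all BH-adjusted per family, 9999
permutations).
"""

import pandas as pd

from _common import RESULTS, SEED, load_data

from gutmtx import multivariate as mv
from gutmtx import pathways as pw
from gutmtx import quantify as qt
from gutmtx.data_model import write_table

N_PERM = 9999


def main() -> None:
    data = load_data()
    filtered, _ = qt.filter_low_expression(data)
    expr = qt.rpkm(filtered)
    taxa = qt.taxon_abundance(expr, filtered.annotations, filtered.taxa)
    labels = {
        "genotype": filtered.samples["genotype"].to_numpy(),
        "diet": filtered.samples["diet"].to_numpy(),
    }
    overall = mv.permanova(mv.distance(taxa.T), labels, n_perm=N_PERM, seed=SEED)
    overall.insert(0, "response", "taxon_abundance")
    rows = [overall]
    for taxon in taxa.index:
        if (taxa.loc[taxon] == 0).all():
            continue
        res = mv.permanova(
            mv.distance(taxa.loc[[taxon]].T, metric="euclidean"),
            labels,
            n_perm=N_PERM,
            seed=SEED,
        )
        res.insert(0, "response", taxon)
        rows.append(res)
    table = pd.concat(rows, ignore_index=True)
    table["q"] = pw.bh_adjust(table["p"])
    write_table(table, RESULTS / "permanova.tsv")
    sig = table[table["q"] < 0.05]
    print(f"{len(sig)}/{len(table)} PERMANOVA tests significant at q < 0.05")
    if len(sig):
        print(sig[["response", "factor", "pseudo_F", "p", "q"]].to_string(index=False))

    result = mv.pca(expr.rpkm.T)
    write_table(result.scores.rename_axis("sample_id").reset_index(), RESULTS / "pca_scores.tsv")
    write_table(
        result.variance_fraction.rename_axis("component").reset_index(),
        RESULTS / "pca_variance.tsv",
    )
    print(
        "PC1/PC2 variance fractions: "
        f"{result.variance_fraction.iloc[0]:.3f} / {result.variance_fraction.iloc[1]:.3f}"
    )
    tests = mv.pc_separation_test(result, filtered.samples, n_perm=N_PERM, seed=SEED)
    write_table(tests, RESULTS / "pca_separation.tsv")
    print(tests.to_string(index=False))


if __name__ == "__main__":
    main()
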