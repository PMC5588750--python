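"""Synthetic metatranscriptome datasets with known ground truth.

Emulates the structure of the study design — 16 samples (2 genotypes x
2 diets x 4 replicates), a Firmicutes-dominated composition over 17 taxon
bins, negative-binomially distributed transcript counts with planted
group-specific fold changes, EC annotations, and a planted coordinated
enzyme chain inside a toy pathway — so every downstream stage can be
tested against analytically known truth without any sequencing data.

Counts for sample (g, d, r) of transcript t are drawn

    NB(mean = s_gdr * mu_t * 2**(g*G_t + d*D_t + g*d*I_t), dispersion = phi)

where s_gdr is the per-sample depth factor and (G, D, I) are the
genotype / diet / interaction effects on the log2 scale.  Effects are
additive over the 2x2 factorial, so each of the four pairwise comparisons
has an analytically known true fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import DEFAULT_TAXA, UNASSIGNED, AnnotatedCounts, save_dataset
from .pathways import write_edge_list, write_kgml

__all__ = ["SynthConfig", "GroundTruth", "generate_dataset", "generate_pathway_fixture"]

#: Firmicutes-dominated default composition over the 17 bins (sums to 1).
DEFAULT_COMPOSITION: tuple[float, ...] = (
    0.30,  # Lachnospiraceae
    0.12,  # Clostridiaceae
    0.10,  # Ruminococcaceae
    0.05,  # Eubacteriaceae
    0.05,  # Oscillospiraceae
    0.10,  # other Firmicutes
    0.05,  # other Clostridia
    0.03,  # Bacilli
    0.06,  # Bacteroidaceae
    0.03,  # Porphyromonadaceae
    0.02,  # Rikenellaceae
    0.03,  # other Bacteroidales
    0.02,  # Deltaproteobacteria
    0.02,  # other Proteobacteria
    0.01,  # Actinobacteria
    0.005,  # Verrucomicrobia
    0.005,  # other bacteria
)


@dataclass(frozen=True)
class SynthConfig:
    """Tunable description of a synthetic dataset.

    Defaults mirror the emulated study design: 4 replicates per
    genotype/diet group, log-normal transcript lengths with median 900 bp,
    NB dispersion 0.2, 5% of transcripts differential per factor with
    |log2FC| ~ Uniform(2, 5) and random sign, 30% of transcripts carrying
    an EC number, and a planted 5-enzyme chain sharing one effect sign.
    """

    n_replicates: int = 4
    n_transcripts: int = 5000
    taxon_composition: tuple[float, ...] = DEFAULT_COMPOSITION
    taxa: tuple[str, ...] = DEFAULT_TAXA
    length_log_median: float = np.log(900.0)  # bp
    length_log_sigma: float = 0.6
    mean_log_median: float = np.log(40.0)  # baseline counts per transcript
    mean_log_sigma: float = 1.3
    depth_log_sigma: float = 0.15  # spread of per-sample depth factors
    depth_factors: tuple[float, ...] | None = None  # overrides the log-normal draw
    phi: float = 0.2  # NB dispersion, var = mu + phi*mu^2
    pi_de: float = 0.05  # fraction differential per factor (genotype, diet)
    pi_interaction: float = 0.0
    effect_low: float = 2.0  # |log2FC| ~ Uniform(effect_low, effect_high)
    effect_high: float = 5.0
    ec_fraction: float = 0.3
    n_chains: int = 4  # chains in the bundled pathway fixture
    fixture_chain_length: int | None = None  # defaults to planted_chain_length
    planted_chain_length: int = 5
    planted_effect_log2: float = 3.0  # genotype effect shared by the chain
    planted_mean: float = 500.0  # baseline mean of chain transcripts
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.taxon_composition, dtype=float)
        if comp.size != len(self.taxa):
            raise ValueError("taxon_composition must have one entry per taxon")
        if not np.isclose(comp.sum(), 1.0):
            raise ValueError("taxon_composition must sum to 1")
        for name in ("pi_de", "pi_interaction", "ec_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be positive")

    @property
    def n_samples(self) -> int:
        return 4 * self.n_replicates


@dataclass
class GroundTruth:
    """Planted truth for a generated dataset.

    ``transcripts`` carries per-transcript true log2 effects
    (genotype/diet/interaction), the derived true log2 fold change of each
    of the four comparisons (group 2 relative to group 1), and a
    differential flag per comparison (true iff that comparison's true
    |log2FC| > 0).  ``chain_ecs``/``chain_sign`` describe the planted
    coordinated enzyme chain.
    """

    transcripts: pd.DataFrame
    chain_ecs: tuple[str, ...]
    chain_sign: int
    pathway: nx.DiGraph


def generate_pathway_fixture(n_chains: int, chain_length: int) -> nx.DiGraph:
    """Toy pathway: ``n_chains`` disjoint directed EC chains of ``chain_length``.

    EC identifiers follow the 4-field pattern ``1.2.<chain>.<step>``.
    """
    if n_chains < 1 or chain_length < 1:
        raise ValueError("n_chains and chain_length must be >= 1")
    graph = nx.DiGraph(pathway_id="path:syn00001", name="synthetic pathway fixture")
    for c in range(n_chains):
        ecs = [f"1.2.{c + 1}.{i + 1}" for i in range(chain_length)]
        graph.add_nodes_from(ecs)
        graph.add_edges_from(zip(ecs[:-1], ecs[1:]))
    return graph


def _comparison_truth(effects: pd.DataFrame) -> pd.DataFrame:
    """True log2FC of group 2 relative to group 1 for the four comparisons.

    Group means are mu * 2**(g*G + d*D + g*d*I) with g=1 for Plin2 and d=1
    for HF, and group 1 is the first-named group of each comparison.
    """
    G, D, I = (effects[c] for c in ("log2fc_genotype", "log2fc_diet", "log2fc_interaction"))
    truth = pd.DataFrame(index=effects.index)
    truth["log2fc_Geno-HF"] = -(G + I)  # Plin2-HF vs WT-HF
    truth["log2fc_Geno-LF"] = -G  # Plin2-LF vs WT-LF
    truth["log2fc_Diet-Plin2"] = -(D + I)  # Plin2-HF vs Plin2-LF
    truth["log2fc_Diet-WT"] = -D  # WT-HF vs WT-LF
    for name in ("Geno-HF", "Geno-LF", "Diet-Plin2", "Diet-WT"):
        truth[f"de_{name}"] = truth[f"log2fc_{name}"].abs() > 0
    return truth


def generate_dataset(config: SynthConfig) -> tuple[AnnotatedCounts, GroundTruth]:
    """Draw a full dataset plus its ground truth; identical config+seed
    yields byte-identical outputs.

    Randomness comes from one seed; independent sub-streams are split
    deterministically per generation component so the result does not
    depend on evaluation order.
    """
    n_t, n_s = config.n_transcripts, config.n_samples
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_annot, rng_len, rng_mean, rng_eff, rng_depth, rng_counts, rng_ec = (
        np.random.default_rng(s) for s in streams
    )

    fixture_len = config.fixture_chain_length or config.planted_chain_length
    if config.planted_chain_length > fixture_len:
        raise ValueError(
            "planted_chain_length exceeds the ECs available per chain in the "
            "bundled pathway fixture"
        )
    pathway = generate_pathway_fixture(config.n_chains, fixture_len)
    fixture_ecs = sorted(pathway.nodes)
    # plant along the first chain of the fixture
    chain_ecs = tuple(f"1.2.1.{i + 1}" for i in range(config.planted_chain_length))
    n_chain = len(chain_ecs)
    if n_chain > n_t:
        raise ValueError("planted chain needs more transcripts than configured")

    transcript_ids = [f"T{i:06d}" for i in range(n_t)]

    # --- annotations ----------------------------------------------------
    taxa_idx = rng_annot.choice(len(config.taxa), size=n_t, p=np.asarray(config.taxon_composition))
    taxa = np.asarray(config.taxa, dtype=object)[taxa_idx]
    lengths = np.maximum(
        np.rint(
            np.exp(rng_len.normal(config.length_log_median, config.length_log_sigma, n_t))
        ).astype(np.int64),
        100,
    )
    # EC assignment: the last n_chain transcripts carry the planted chain,
    # one EC each; other EC-bearing transcripts draw from the remaining
    # fixture ECs plus a pool of off-pathway ECs.
    ecs: list[frozenset[str]] = []
    off_pathway = [f"3.{a + 1}.{b + 1}.{c + 1}" for a in range(4) for b in range(5) for c in range(5)]
    pool = [ec for ec in fixture_ecs if ec not in chain_ecs] + off_pathway
    has_ec = rng_ec.random(n_t) < config.ec_fraction
    pool_draws = rng_ec.choice(len(pool), size=n_t)
    for i in range(n_t - n_chain):
        ecs.append(frozenset({pool[pool_draws[i]]}) if has_ec[i] else frozenset())
    for ec in chain_ecs:
        ecs.append(frozenset({ec}))

    annotations = pd.DataFrame(
        {
            "taxon": taxa,
            "ec_numbers": ecs,
            "length_bp": lengths,
        },
        index=pd.Index(transcript_ids, name="transcript_id"),
    )

    # --- effects --------------------------------------------------------
    def draw_effects(rate: float) -> np.ndarray:
        flag = rng_eff.random(n_t) < rate
        mag = rng_eff.uniform(config.effect_low, config.effect_high, n_t)
        sign = rng_eff.choice([-1.0, 1.0], size=n_t)
        return np.where(flag, sign * mag, 0.0)

    eff_g = draw_effects(config.pi_de)
    eff_d = draw_effects(config.pi_de)
    eff_i = draw_effects(config.pi_interaction)

    mu = np.exp(rng_mean.normal(config.mean_log_median, config.mean_log_sigma, n_t))
    # planted chain: shared-sign genotype effect, fixed strong baseline,
    # no diet/interaction effect.  pi_de = 0 means a fully null dataset:
    # nothing is differential, the chain included.
    chain_sign = 1
    chain_slice = slice(n_t - n_chain, n_t)
    planted_effect = config.planted_effect_log2 if config.pi_de > 0 else 0.0
    eff_g[chain_slice] = chain_sign * planted_effect
    eff_d[chain_slice] = 0.0
    eff_i[chain_slice] = 0.0
    mu[chain_slice] = config.planted_mean

    effects = pd.DataFrame(
        {
            "log2fc_genotype": eff_g,
            "log2fc_diet": eff_d,
            "log2fc_interaction": eff_i,
        },
        index=annotations.index,
    )

    # --- samples --------------------------------------------------------
    groups = [("Plin2", "HF"), ("WT", "HF"), ("Plin2", "LF"), ("WT", "LF")]
    sample_rows = []
    for genotype, diet in groups:
        for r in range(1, config.n_replicates + 1):
            sample_rows.append((f"{genotype}-{diet}-{r}", genotype, diet, r))
    sample_ids = [row[0] for row in sample_rows]
    if config.depth_factors is not None:
        depth = np.asarray(config.depth_factors, dtype=float)
        if depth.size != n_s:
            raise ValueError("depth_factors must have one entry per sample")
    else:
        depth = np.exp(rng_depth.normal(0.0, config.depth_log_sigma, n_s))

    # --- counts ---------------------------------------------------------
    g_ind = np.array([1.0 if g == "Plin2" else 0.0 for _, g, _, _ in sample_rows])
    d_ind = np.array([1.0 if d == "HF" else 0.0 for _, _, d, _ in sample_rows])
    log2_shift = (
        np.outer(eff_g, g_ind) + np.outer(eff_d, d_ind) + np.outer(eff_i, g_ind * d_ind)
    )
    mean = depth[None, :] * mu[:, None] * np.exp2(log2_shift)
    # NB with var = m + phi*m^2: size r = 1/phi, p = r/(r+m)
    r = 1.0 / config.phi
    counts = rng_counts.negative_binomial(r, r / (r + mean))

    samples = pd.DataFrame(
        {
            "genotype": [g for _, g, _, _ in sample_rows],
            "diet": [d for _, _, d, _ in sample_rows],
            "replicate": [rep for _, _, _, rep in sample_rows],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    data = AnnotatedCounts(
        counts=pd.DataFrame(counts, index=annotations.index, columns=sample_ids),
        annotations=annotations,
        samples=samples,
        taxa=config.taxa,
    )

    truth_df = pd.concat([effects, _comparison_truth(effects)], axis=1)
    truth = GroundTruth(
        transcripts=truth_df,
        chain_ecs=chain_ecs,
        chain_sign=chain_sign,
        pathway=pathway,
    )
    return data, truth


def save_synthetic(
    data: AnnotatedCounts, truth: GroundTruth, outdir: str | Path
) -> dict[str, Path]:
    """Write the dataset TSVs plus ground_truth.tsv and the pathway fixture."""
    outdir = Path(outdir)
    paths = save_dataset(data, outdir)
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    truth.transcripts.rename_axis("transcript_id").reset_index().to_csv(
        paths["ground_truth"], sep="\t", index=False, float_format="%.12g"
    )
    paths["pathway_kgml"] = outdir / "pathway.kgml"
    paths["pathway_edges"] = outdir / "pathway_edges.tsv"
    write_kgml(truth.pathway, paths["pathway_kgml"])
    write_edge_list(truth.pathway, paths["pathway_edges"])
    (outdir / "planted_chain.tsv").write_text(
        "ec\tsign\n" + "".join(f"{ec}\t{truth.chain_sign}\n" for ec in truth.chain_ecs)
    )
    paths["planted_chain"] = outdir / "planted_chain.tsv"
    return paths
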