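"""Gene-set enrichment and KEGG pathway-graph analysis.

Two halves:

* hypergeometric enrichment of significant transcripts in taxa, and of
  significant enzymes in pathways, against the full transcript/enzyme
  universe observed across all samples, with Benjamini-Hochberg FDR;
* pathway graphs built from KGML (or a simplified edge-list dialect) whose
  nodes are EC numbers and whose directed edges connect enzymes where one
  reaction's product is another's substrate — the structure on which
  coordinated runs of consecutive same-direction enzymes are detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lxml import etree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "hypergeom_enrich",
    "build_pathway_graph",
    "write_kgml",
    "write_edge_list",
    "find_coordinated_runs",
    "CoordinatedRun",
    "taxon_direction_tally",
    "export_cytoscape",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    memberships: Mapping[str, set],
    universe: set,
    draws: set,
    min_set: int = 2,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``draws`` in each set.

    For each set with at least ``min_set`` members in the universe,
    p = P(X >= k) with X ~ Hypergeometric(N, K, n), where N = |universe|,
    K = members of the set in the universe, n = |draws| and k = drawn
    members of the set.  Sets with K < ``min_set`` are excluded before BH
    adjustment.  Returns columns set_id, N, K, n, k, p, q.
    """
    if not draws <= universe:
        raise ValueError("draws must be a subset of the universe")
    N, n = len(universe), len(draws)
    rows = []
    for set_id in sorted(memberships):
        members = memberships[set_id] & universe
        K = len(members)
        if K < min_set:
            continue
        k = len(members & draws)
        p = 1.0 if n == 0 else float(hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, N, K, n, k, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=["set_id", "N", "K", "n", "k", "p"])
    result["q"] = bh_adjust(result["p"]) if len(result) else []
    return result


# ---------------------------------------------------------------------------
# pathway graphs
# ---------------------------------------------------------------------------


def build_pathway_graph(path: str | Path) -> nx.DiGraph:
    """Parse a pathway definition into an EC-node directed graph.

    Accepts KGML (enzyme entries + reactions; two enzymes become adjacent
    when one reaction's product compound is the other's substrate; every
    adjacency mediated by a reversible reaction is emitted in both
    directions) or the simplified edge-list dialect: one ``EC<TAB>EC`` line
    per directed edge, a bare ``EC`` line per isolated enzyme, ``#``
    comments.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("<"):
        return _parse_kgml(path)
    return _parse_edge_list(text, name=path.stem)


def _parse_edge_list(text: str, name: str = "pathway") -> nx.DiGraph:
    graph = nx.DiGraph(pathway_id=name, name=name)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            graph.add_node(fields[0])
        else:
            u, v = fields[0], fields[1]
            if u != v:
                graph.add_edge(u, v)
    return graph


def _parse_kgml(path: Path) -> nx.DiGraph:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed KGML ({exc})") from exc
    root = tree.getroot()
    graph = nx.DiGraph(
        pathway_id=root.get("name", "pathway"),
        name=root.get("title", root.get("name", "pathway")),
    )
    # reaction name -> ECs of the enzyme entries catalysing it
    reaction_ecs: dict[str, list[str]] = {}
    found_ec = False
    for entry in root.findall("entry"):
        if entry.get("type") != "enzyme":
            continue
        ecs = [
            token.split(":", 1)[1]
            for token in (entry.get("name") or "").split()
            if token.startswith("ec:")
        ]
        if not ecs:
            continue
        found_ec = True
        graph.add_nodes_from(ecs)
        for rn in (entry.get("reaction") or "").split():
            reaction_ecs.setdefault(rn, []).extend(ecs)
    if not found_ec:
        raise ValueError(
            f"{path}: KGML contains no enzyme entries with EC annotations; "
            "consider the simplified edge-list dialect"
        )
    reactions = []  # (ecs, substrates, products, reversible)
    for reaction in root.findall("reaction"):
        rn = reaction.get("name", "")
        ecs = reaction_ecs.get(rn, [])
        subs = [s.get("name") for s in reaction.findall("substrate")]
        prods = [p.get("name") for p in reaction.findall("product")]
        reactions.append((ecs, subs, prods, reaction.get("type") == "reversible"))
    for ecs_a, _, prods_a, rev_a in reactions:
        for ecs_b, subs_b, _, rev_b in reactions:
            if not set(prods_a) & set(subs_b):
                continue
            for u in ecs_a:
                for v in ecs_b:
                    if u == v:
                        continue
                    graph.add_edge(u, v)
                    if rev_a or rev_b:
                        graph.add_edge(v, u)
    return graph


def write_kgml(graph: nx.DiGraph, path: str | Path) -> None:
    """Serialize an EC chain/graph as minimal valid KGML.

    Each node becomes an enzyme entry with its own reaction; each edge
    u -> v is realized by a shared compound that u's reaction produces and
    v's reaction consumes.
    """
    pathway_id = graph.graph.get("pathway_id", "path:syn00001")
    root = etree.Element(
        "pathway",
        name=str(pathway_id),
        org="syn",
        number="00001",
        title=str(graph.graph.get("name", "synthetic pathway")),
    )
    nodes = sorted(graph.nodes)
    node_idx = {ec: i for i, ec in enumerate(nodes)}
    # one private substrate compound per node; edge u->v reuses u's product
    # compound as v's substrate
    edge_cpd = {
        (u, v): f"cpd:E{node_idx[u]:04d}_{node_idx[v]:04d}" for u, v in graph.edges
    }
    for i, ec in enumerate(nodes):
        etree.SubElement(
            root,
            "entry",
            id=str(i + 1),
            name=f"ec:{ec}",
            type="enzyme",
            reaction=f"rn:R{i + 1:05d}",
        )
    for i, ec in enumerate(nodes):
        reaction = etree.SubElement(
            root,
            "reaction",
            id=str(i + 1),
            name=f"rn:R{i + 1:05d}",
            type="irreversible",
        )
        substrates = [edge_cpd[(u, v)] for u, v in graph.in_edges(ec)] or [
            f"cpd:S{i:04d}"
        ]
        products = [edge_cpd[(u, v)] for u, v in graph.out_edges(ec)] or [
            f"cpd:P{i:04d}"
        ]
        for name in substrates:
            etree.SubElement(reaction, "substrate", id=name, name=name)
        for name in products:
            etree.SubElement(reaction, "product", id=name, name=name)
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


def write_edge_list(graph: nx.DiGraph, path: str | Path) -> None:
    """Serialize in the simplified edge-list dialect (see build_pathway_graph)."""
    lines = [f"# pathway: {graph.graph.get('pathway_id', 'pathway')}"]
    isolated = [n for n in sorted(graph.nodes) if graph.degree(n) == 0]
    lines += [f"{u}\t{v}" for u, v in sorted(graph.edges)]
    lines += isolated
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinated consecutive-enzyme runs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoordinatedRun:
    """A maximal directed path of pathway-adjacent enzymes whose aeFC values
    all share one sign — the formalization of coordinated expression of
    consecutive enzymes with the potential to channel metabolites."""

    ecs: tuple[str, ...]
    direction: str  # "up" or "down"
    mean_abs_aefc: float
    comparison: str = ""

    @property
    def length(self) -> int:
        return len(self.ecs)


def find_coordinated_runs(
    graph: nx.DiGraph,
    enzyme_values: Mapping[str, float],
    min_len: int = 3,
    comparison: str = "",
) -> list[CoordinatedRun]:
    """All maximal same-sign directed paths of length >= ``min_len``.

    ``enzyme_values`` maps EC -> aeFC; enzymes that are missing or have a
    zero value break runs.  A path is maximal when it cannot be extended at
    either end by another node of the same sign.  Output order is
    deterministic (lexicographic by EC list).  Cyclic same-sign components
    are reported as their longest simple path with a warning.
    """
    runs: list[CoordinatedRun] = []
    for sign, direction in ((1, "up"), (-1, "down")):
        keep = [
            ec
            for ec in graph.nodes
            if ec in enzyme_values
            and enzyme_values[ec] != 0
            and np.sign(enzyme_values[ec]) == sign
        ]
        sub = graph.subgraph(keep)
        if not sub:
            continue
        if not nx.is_directed_acyclic_graph(sub):
            warnings.warn(
                f"cyclic same-sign ({direction}) component; reporting longest "
                "simple paths only",
                stacklevel=2,
            )
            paths = _longest_paths_cyclic(sub)
        else:
            paths = _maximal_paths_dag(sub)
        for path in paths:
            if len(path) < min_len:
                continue
            vals = [abs(enzyme_values[ec]) for ec in path]
            runs.append(
                CoordinatedRun(tuple(path), direction, float(np.mean(vals)), comparison)
            )
    runs.sort(key=lambda r: r.ecs)
    return runs


def _maximal_paths_dag(sub: nx.DiGraph) -> list[list[str]]:
    sources = [n for n in sub.nodes if sub.in_degree(n) == 0]
    sinks = {n for n in sub.nodes if sub.out_degree(n) == 0}
    paths: list[list[str]] = []
    for s in sources:
        if s in sinks:  # isolated node: trivially maximal
            paths.append([s])
            continue
        stack: list[list[str]] = [[s]]
        while stack:
            path = stack.pop()
            tail = path[-1]
            if tail in sinks:
                paths.append(path)
                continue
            for nxt in sorted(sub.successors(tail)):
                if nxt not in path:
                    stack.append(path + [nxt])
    return paths


def _longest_paths_cyclic(sub: nx.DiGraph) -> list[list[str]]:
    # exhaustive over simple paths; pathway graphs are small
    best: list[list[str]] = []
    nodes = sorted(sub.nodes)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            for path in nx.all_simple_paths(sub, s, t):
                if not best or len(path) > len(best[0]):
                    best = [path]
                elif len(path) == len(best[0]) and path not in best:
                    best.append(path)
    return best or [[n] for n in nodes[:1]]


def taxon_direction_tally(
    path_ecs: Sequence[str], taxon_aefc: pd.DataFrame
) -> pd.DataFrame:
    """Per-taxon counts of up/down/absent enzymes along a pathway path.

    ``taxon_aefc`` is an EC x taxon matrix of taxon-restricted aeFC values
    (NaN where the taxon expresses no member transcript of that enzyme).
    Returns a taxon-indexed frame with columns n_up, n_down, n_absent that
    sum to ``len(path_ecs)`` for every taxon.
    """
    missing = [ec for ec in path_ecs if ec not in taxon_aefc.index]
    if missing:
        raise KeyError(f"path ECs absent from the matrix: {missing}")
    block = taxon_aefc.loc[list(path_ecs)]
    return pd.DataFrame(
        {
            "n_up": (block > 0).sum(),
            "n_down": (block < 0).sum(),
            "n_absent": block.isna().sum(),
        }
    )


def export_cytoscape(
    graph: nx.DiGraph,
    enzyme_values: Mapping[str, float],
    significant: Iterable[str],
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write GraphML and SIF files with aeFC / significance node attributes."""
    out_prefix = Path(out_prefix)
    sig = set(significant)
    export = graph.copy()
    for node in export.nodes:
        export.nodes[node]["aeFC"] = float(enzyme_values.get(node, float("nan")))
        export.nodes[node]["significant"] = node in sig
    paths = {
        "graphml": out_prefix.with_suffix(".graphml"),
        "sif": out_prefix.with_suffix(".sif"),
    }
    nx.write_graphml(export, paths["graphml"])
    with open(paths["sif"], "w") as fh:
        for u, v in sorted(export.edges):
            fh.write(f"{u}\treaction\t{v}\n")
        for n in sorted(export.nodes):
            if export.degree(n) == 0:
                fh.write(f"{n}\n")
    return paths
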