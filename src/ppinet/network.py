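"""Interactome graph analyses: pathway crosstalk statistics and topology.

The crosstalk battery mirrors the standard hormone-signaling analysis:

* *overlap test* — are the interactor sets of two pathways shared more than
  expected among the network's proteins?  One-sided Fisher's exact test on
  the 2x2 table [[X12, X2-X12], [X1-X12, N - X1 - X2 + X12]] with N the
  number of proteins in the network.
* *link enrichment* — are direct edges between the core components of two
  pathways more frequent than in degree-preserving randomized networks?
  Fold = observed / mean over R edge-shuffled replicates, with an empirical
  p-value using the +1 correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections.abc import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GoAnnotationSet
from .pairs import Pair, PathwayCoreSet, canonical_pair

logger = logging.getLogger(__name__)


class InteractionNetwork:
    """Undirected simple graph of predicted interactions."""

    def __init__(self, graph: nx.Graph):
        graph.remove_edges_from(nx.selfloop_edges(graph))
        self.graph = graph

    @classmethod
    def from_pairs(cls, pairs: Iterable[Pair]) -> "InteractionNetwork":
        graph = nx.Graph()
        graph.add_edges_from(canonical_pair(a, b) for a, b in pairs)
        return cls(graph)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_proteins(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_interactions(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return self.graph.edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


# ---------------------------------------------------------------------------
# pathway interactors and the Fisher overlap test


def pathway_interactors(
    network: InteractionNetwork, cores: PathwayCoreSet, *, include_cores: bool = False
) -> set[str]:
    """Proteins interacting with any core protein of the pathway.

    Core proteins themselves are excluded unless ``include_cores``; cores
    absent from the network are logged.
    """
    graph = network.graph
    present = cores.cores & set(graph.nodes)
    if not present:
        raise ValueError(f"no core protein of pathway {cores.name!r} is in the network")
    missing = cores.cores - present
    if missing:
        logger.info("pathway %s: %d cores absent from network", cores.name, len(missing))
    interactors: set[str] = set()
    for core in present:
        interactors |= set(graph.neighbors(core))
    if not include_cores:
        interactors -= cores.cores
    return interactors


@dataclass
class OverlapTest:
    x1: int
    x2: int
    x12: int
    n_network: int
    p_value: float
    odds_ratio: float

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.x12, self.x2 - self.x12],
            [self.x1 - self.x12, self.n_network - self.x1 - self.x2 + self.x12],
        ]


def fisher_overlap_pvalue(x12, x1, x2, n_network):
    """One-sided (enrichment) Fisher p for overlap tables; vectorised.

    P(overlap >= x12) under the hypergeometric null of drawing x2 of
    n_network proteins and counting hits among the x1 pathway-1 proteins.
    """
    x12, x1, x2, n = (np.asarray(v) for v in (x12, x1, x2, n_network))
    return stats.hypergeom.sf(x12 - 1, n, x1, x2)


def overlap_fisher(set_a: set[str], set_b: set[str], n_network: int) -> OverlapTest:
    """Fisher's exact test for interactor-set overlap between two pathways."""
    x1, x2 = len(set_a), len(set_b)
    x12 = len(set_a & set_b)
    if x1 > n_network or x2 > n_network or n_network - x1 - x2 + x12 < 0:
        raise ValueError("set sizes inconsistent with the network protein count")
    p = float(fisher_overlap_pvalue(x12, x1, x2, n_network))
    table = [[x12, x2 - x12], [x1 - x12, n_network - x1 - x2 + x12]]
    numer = table[0][0] * table[1][1]
    denom = table[0][1] * table[1][0]
    odds = numer / denom if denom else math.inf
    return OverlapTest(x1=x1, x2=x2, x12=x12, n_network=n_network, p_value=p, odds_ratio=odds)


def overlap_matrix(
    network: InteractionNetwork, pathways: list[PathwayCoreSet], *, include_cores: bool = False
) -> pd.DataFrame:
    """Pairwise interactor-overlap summary: counts above the diagonal,
    Fisher p below, interactor-set sizes on the diagonal."""
    sets = {p.name: pathway_interactors(network, p, include_cores=include_cores) for p in pathways}
    names = [p.name for p in pathways]
    out = pd.DataFrame(np.nan, index=names, columns=names)
    n_net = network.n_proteins
    for i, a in enumerate(names):
        out.loc[a, a] = len(sets[a])
        for b in names[i + 1 :]:
            test = overlap_fisher(sets[a], sets[b], n_net)
            out.loc[a, b] = test.x12
            out.loc[b, a] = test.p_value
    return out


# ---------------------------------------------------------------------------
# degree-preserving randomization and link enrichment


def edge_shuffle_null(
    network: InteractionNetwork,
    r: int = 1000,
    seed: int = 0,
    *,
    swaps_per_edge: int = 10,
) -> Iterator[nx.Graph]:
    """Stream R degree-preserving randomizations of the network.

    Each replicate applies ``swaps_per_edge * |E|`` accepted double-edge
    swaps (rejecting self-loops and multi-edges), which preserves every
    node's degree exactly.  Graphs admitting no swap are yielded unchanged
    with a warning.
    """
    if network.n_interactions < 2:
        raise ValueError("randomization needs at least 2 edges")
    n_swaps = swaps_per_edge * network.n_interactions
    for i in range(r):
        replicate = network.graph.copy()
        try:
            nx.double_edge_swap(
                replicate, nswap=n_swaps, max_tries=100 * n_swaps, seed=seed + i
            )
        except nx.NetworkXAlgorithmError:
            logger.warning("replicate %d: swap budget exhausted before %d swaps", i, n_swaps)
        except nx.NetworkXError:
            logger.warning("replicate %d: graph admits no degree-preserving swap", i)
        yield replicate


@dataclass
class EnrichmentTest:
    observed: int
    null_counts: np.ndarray
    fold: float
    p_value: float
    infinite_fold: bool = False


def _cross_links(graph: nx.Graph, cores_a: set[str], cores_b: set[str]) -> int:
    """Edges with one endpoint in cores_a and the other in cores_b.

    Edges internal to the intersection count once.
    """
    count = 0
    for u, v in graph.edges():
        if (u in cores_a and v in cores_b) or (v in cores_a and u in cores_b):
            count += 1
    return count


def interaction_enrichment(
    network: InteractionNetwork,
    cores_a: PathwayCoreSet | set[str],
    cores_b: PathwayCoreSet | set[str],
    r: int = 1000,
    seed: int = 0,
) -> EnrichmentTest:
    """Fold enrichment of direct links between two pathways' core proteins.

    Observed cross-links divided by their mean over R degree-preserving
    randomized networks; empirical p = (1 + #{null >= observed}) / (R + 1).
    """
    if r < 1:
        raise ValueError("need at least one randomization")
    set_a = cores_a.cores if isinstance(cores_a, PathwayCoreSet) else set(cores_a)
    set_b = cores_b.cores if isinstance(cores_b, PathwayCoreSet) else set(cores_b)
    observed = _cross_links(network.graph, set_a, set_b)
    null = np.array(
        [_cross_links(g, set_a, set_b) for g in edge_shuffle_null(network, r, seed)],
        dtype=float,
    )
    mean_null = null.mean()
    if mean_null == 0:
        fold, infinite = (0.0, False) if observed == 0 else (math.inf, True)
    else:
        fold, infinite = observed / mean_null, False
    p = (1 + int((null >= observed).sum())) / (r + 1)
    return EnrichmentTest(
        observed=observed, null_counts=null, fold=fold, p_value=p, infinite_fold=infinite
    )


def interaction_enrichment_matrix(
    network: InteractionNetwork,
    pathways: list[PathwayCoreSet],
    r: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Core-link fold enrichment for every pathway pair over one shared null.

    The R randomized replicates are generated once and every pathway pair
    is counted on each replicate.  Returns (fold, empirical p) matrices.
    """
    names = [p.name for p in pathways]
    cores = {p.name: p.cores for p in pathways}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i:]]
    observed = {
        key: _cross_links(network.graph, cores[key[0]], cores[key[1]]) for key in pairs
    }
    null_counts = {key: np.zeros(r) for key in pairs}
    for rep, graph in enumerate(edge_shuffle_null(network, r, seed)):
        for key in pairs:
            null_counts[key][rep] = _cross_links(graph, cores[key[0]], cores[key[1]])
    fold = pd.DataFrame(np.nan, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), obs in observed.items():
        null = null_counts[(a, b)]
        mean_null = null.mean()
        f = obs / mean_null if mean_null else (math.inf if obs else 0.0)
        p = (1 + int((null >= obs).sum())) / (r + 1)
        fold.loc[a, b] = fold.loc[b, a] = f
        pval.loc[a, b] = pval.loc[b, a] = p
    return fold, pval


# ---------------------------------------------------------------------------
# GO term enrichment (hypergeometric + Benjamini-Hochberg)


def go_term_enrichment(
    proteins: set[str],
    annot: GoAnnotationSet,
    *,
    aspect: str = "BP",
    background: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of GO terms in a protein set.

    Background defaults to all genes annotated in the aspect.  Returns a
    table sorted by p with Benjamini-Hochberg FDR.
    """
    if not proteins:
        raise ValueError("empty protein set")
    closed = annot.closed_terms(aspect)
    if background is None:
        background = set(closed)
    study = proteins & background
    n_bg, n_study = len(background), len(study)
    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in closed.get(gene, ()):
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    rows = []
    for term, k_bg in sorted(term_bg.items()):
        k_study = term_study.get(term, 0)
        p = float(stats.hypergeom.sf(k_study - 1, n_bg, k_bg, n_study)) if k_study else 1.0
        rows.append({"term": term, "study_count": k_study, "background_count": k_bg, "p": p})
    table = pd.DataFrame(rows).set_index("term").sort_values(["p", "study_count"])
    m = len(table)
    ranked = table["p"].to_numpy() * m / np.arange(1, m + 1)
    table["fdr"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    return table


# ---------------------------------------------------------------------------
# topology


@dataclass
class TopologySummary:
    degree_histogram: pd.Series
    powerlaw_slope: float
    average_clustering: float


def topology_summary(network: InteractionNetwork) -> TopologySummary:
    """Degree distribution, log-log power-law slope, average clustering.

    The slope is a least-squares fit of log10 frequency on log10 degree
    over non-zero degrees — a scale-free network yields a negative slope.
    """
    if network.n_proteins < 3:
        raise ValueError("topology summary needs at least 3 proteins")
    degrees = np.array([d for _, d in network.graph.degree()])
    values, counts = np.unique(degrees[degrees > 0], return_counts=True)
    histogram = pd.Series(counts, index=values, name="count")
    if len(values) > 1:
        slope = float(np.polyfit(np.log10(values), np.log10(counts), 1)[0])
    else:
        slope = float("nan")
    return TopologySummary(
        degree_histogram=histogram,
        powerlaw_slope=slope,
        average_clustering=float(nx.average_clustering(network.graph)),
    )
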