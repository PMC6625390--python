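"""Genomic-context interaction features for a protein pair.

Seven features are computed per pair:

1. co-expression: Pearson correlation of log2(RPKM+1) profiles across
   RNA-Seq samples;
2-4. GO functional similarity S = log(n/N) / log(2/N) for each of the BP,
   MF and CC ontologies, where n is the annotated-gene count of the lowest
   (most specific) GO class containing both genes and N the genome
   annotation size.  S is 1 when the lowest common class holds exactly the
   two genes and 0 at the root;
5. phylogenetic-profile similarity: Pearson (phi) correlation of the two
   genes' presence/absence vectors across a genome panel;
6. interolog support: the number of model organisms (of E. coli, yeast,
   worm, fly, mouse, human) in which orthologs of both genes are known to
   interact;
7. gene fusion (Rosetta stone): 1 if some foreign protein carries
   significant, essentially non-overlapping hits from both genes.

A feature that cannot be computed for a pair is *missing*, never silently
zero; imputation happens later, at the classifier boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairs import Pair

logger = logging.getLogger(__name__)

MISSING = float("nan")

ORGANISMS = ("ecoli", "yeast", "worm", "fly", "mouse", "human")


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionMatrix:
    """RPKM expression values (genes x samples) plus their provenance."""

    rpkm: pd.DataFrame
    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    def log_expression(self) -> pd.DataFrame:
        """log2(RPKM + 1), the scale on which co-expression is computed."""
        return np.log2(self.rpkm + 1.0)


def rpkm(counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series | None = None) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = 1e9 * C / (M * L) with C the read count of the gene in a sample,
    M the sample's total mapped reads and L the transcript length in bp.
    """
    if totals is None:
        totals = counts.sum(axis=0).astype(float)
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if (totals <= 0).any():
        raise ValueError("per-sample mapped totals must be positive")
    values = 1e9 * counts.to_numpy(dtype=float) / np.outer(lengths.to_numpy(), np.ones(counts.shape[1])) / totals.to_numpy()
    out = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(rpkm=out, counts=counts, lengths=lengths, totals=totals)


def coexpression_pcc(expr: ExpressionMatrix, pair: Pair) -> float:
    """Pearson correlation of the pair's log-expression profiles, or NaN.

    Missing when either gene is absent from the matrix, has fewer than 3
    samples, or a constant profile (zero variance).
    """
    log_expr = expr.log_expression()
    a, b = pair
    if a not in log_expr.index or b not in log_expr.index:
        return MISSING
    xa = log_expr.loc[a].to_numpy(dtype=float)
    xb = log_expr.loc[b].to_numpy(dtype=float)
    if xa.size < 3 or np.std(xa) == 0 or np.std(xb) == 0:
        return MISSING
    return float(np.corrcoef(xa, xb)[0, 1])


def coexpression_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlation matrix on log expression (vectorised).

    Genes with constant profiles get NaN rows/columns.
    """
    log_expr = expr.log_expression()
    values = log_expr.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    return pd.DataFrame(corr, index=log_expr.index, columns=log_expr.index)


# ---------------------------------------------------------------------------
# GO functional similarity


@dataclass
class GoAnnotationSet:
    """Per-aspect gene annotations with ancestor closure and term sizes.

    ``direct`` maps aspect -> gene -> directly annotated terms; the closure
    (true-path rule: annotation to a term implies annotation to every
    ancestor) and per-term annotated-gene counts are computed lazily.
    ``genome_size`` is N in the similarity formula; it defaults to the
    number of annotated genes in the loaded set.
    """

    direct: dict[str, dict[str, set[str]]]
    parents: dict[str, set[str]]
    genome_size: int | None = None
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _closed: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict, repr=False)
    _term_counts: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of *term*, inclusive of the term itself."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        closure = {term}
        stack = [term]
        while stack:
            for parent in self.parents.get(stack.pop(), ()):
                if parent not in closure:
                    closure.add(parent)
                    stack.append(parent)
        result = frozenset(closure)
        self._ancestors[term] = result
        return result

    def closed_terms(self, aspect: str) -> dict[str, frozenset[str]]:
        """gene -> annotation closure for one aspect."""
        if aspect not in self._closed:
            closed = {}
            for gene, terms in self.direct.get(aspect, {}).items():
                closure: set[str] = set()
                for term in terms:
                    closure |= self.ancestors(term)
                closed[gene] = frozenset(closure)
            self._closed[aspect] = closed
        return self._closed[aspect]

    def term_counts(self, aspect: str) -> dict[str, int]:
        """term -> number of genes annotated to it (after closure)."""
        if aspect not in self._term_counts:
            counts: dict[str, int] = {}
            for closure in self.closed_terms(aspect).values():
                for term in closure:
                    counts[term] = counts.get(term, 0) + 1
            self._term_counts[aspect] = counts
        return self._term_counts[aspect]

    def n_genes(self) -> int:
        if self.genome_size is not None:
            return self.genome_size
        annotated = set()
        for aspect in self.direct:
            annotated |= set(self.direct[aspect])
        return len(annotated)


def go_similarity(annot: GoAnnotationSet, pair: Pair, aspect: str) -> float:
    """Functional similarity S = log(n/N)/log(2/N) on one ontology aspect.

    n is the annotated-gene count of the lowest common GO class of the two
    genes (minimum count over common ancestors, ties broken by term id); N
    is the genome annotation size.  Missing (NaN) when either gene is
    unannotated or no common class exists.
    """
    closed = annot.closed_terms(aspect)
    a, b = pair
    if a not in closed or b not in closed:
        return MISSING
    common = closed[a] & closed[b]
    if not common:
        return MISSING
    counts = annot.term_counts(aspect)
    # ties on n_t are irrelevant for the value; sort key makes the chosen
    # class deterministic for reporting
    n = min(counts[t] for t in sorted(common))
    N = annot.n_genes()
    n = max(n, 2)  # both genes are members, so the true count is >= 2
    if n >= N:
        return 0.0
    return math.log(n / N) / math.log(2.0 / N)


# ---------------------------------------------------------------------------
# phylogenetic profiles


def phylo_profile_similarity(profiles: pd.DataFrame, pair: Pair) -> float:
    """Pearson (phi) correlation of two presence/absence profiles, or NaN."""
    a, b = pair
    if a not in profiles.index or b not in profiles.index:
        return MISSING
    xa = profiles.loc[a].to_numpy(dtype=float)
    xb = profiles.loc[b].to_numpy(dtype=float)
    if xa.std() == 0 or xb.std() == 0:
        return MISSING
    return float(np.corrcoef(xa, xb)[0, 1])


def phylo_profile_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """All-pairs phi correlation of profiles; constant profiles get NaN."""
    values = profiles.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    return pd.DataFrame(corr, index=profiles.index, columns=profiles.index)


# ---------------------------------------------------------------------------
# interologs


@dataclass
class OrthologMap:
    """organism -> gene -> ortholog group (a function on the query side)."""

    groups: dict[str, dict[str, str]]


@dataclass
class ForeignInteractionSet:
    """organism -> set of canonical ortholog-group pairs known to interact."""

    interactions: dict[str, set[tuple[str, str]]]


def interolog_support(orth: OrthologMap, foreign: ForeignInteractionSet, pair: Pair) -> int:
    """Number of organisms whose orthologs of the two genes interact (0-6)."""
    a, b = pair
    support = 0
    for organism in ORGANISMS:
        mapping = orth.groups.get(organism, {})
        ga, gb = mapping.get(a), mapping.get(b)
        if ga is None or gb is None:
            continue
        key = (ga, gb) if ga <= gb else (gb, ga)
        if key in foreign.interactions.get(organism, ()):
            support += 1
    return support


# ---------------------------------------------------------------------------
# gene fusion (Rosetta stone)

FUSION_EVALUE_CUTOFF = 1e-5
FUSION_OVERLAP_TOLERANCE = 0.10  # fraction of the shorter interval


@dataclass
class FusionHitSet:
    """foreign protein -> query gene -> list of (start, end, e-value) hits."""

    hits: dict[str, dict[str, list[tuple[int, int, float]]]]


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def gene_fusion_flag(
    fusions: FusionHitSet,
    pair: Pair,
    *,
    evalue_cutoff: float = FUSION_EVALUE_CUTOFF,
    overlap_tolerance: float = FUSION_OVERLAP_TOLERANCE,
) -> int:
    """1 if a foreign protein has near-disjoint significant hits from both genes.

    Two hits count as fusion evidence when their intervals on the foreign
    protein overlap by less than ``overlap_tolerance`` of the shorter
    interval (the two genes map to different segments of one fused protein).
    """
    a, b = pair
    for per_gene in fusions.hits.values():
        hits_a = [h for h in per_gene.get(a, ()) if h[2] <= evalue_cutoff]
        hits_b = [h for h in per_gene.get(b, ()) if h[2] <= evalue_cutoff]
        for sa, ea, _ in hits_a:
            len_a = ea - sa + 1
            for sb, eb, _ in hits_b:
                shorter = min(len_a, eb - sb + 1)
                if _interval_overlap((sa, ea), (sb, eb)) < overlap_tolerance * shorter:
                    return 1
    return 0


# ---------------------------------------------------------------------------
# assembly

GENOMIC_FEATURES = (
    "coexpression_pcc",
    "go_bp_sim",
    "go_mf_sim",
    "go_cc_sim",
    "phylo_profile_sim",
    "interolog_support",
    "gene_fusion",
)


def assemble_genomic_features(
    pair: Pair,
    *,
    expr: ExpressionMatrix | None = None,
    annot: GoAnnotationSet | None = None,
    profiles: pd.DataFrame | None = None,
    orthologs: OrthologMap | None = None,
    foreign: ForeignInteractionSet | None = None,
    fusions: FusionHitSet | None = None,
) -> dict[str, float]:
    """All seven genomic features for one pair; absent sources yield NaN.

    ``interolog_support`` and ``gene_fusion`` are 0 (not missing) whenever
    their evidence sources are loaded: absence of evidence is their value.
    """
    out = {name: MISSING for name in GENOMIC_FEATURES}
    if expr is not None:
        out["coexpression_pcc"] = coexpression_pcc(expr, pair)
    if annot is not None:
        out["go_bp_sim"] = go_similarity(annot, pair, "BP")
        out["go_mf_sim"] = go_similarity(annot, pair, "MF")
        out["go_cc_sim"] = go_similarity(annot, pair, "CC")
    if profiles is not None:
        out["phylo_profile_sim"] = phylo_profile_similarity(profiles, pair)
    if orthologs is not None and foreign is not None:
        out["interolog_support"] = float(interolog_support(orthologs, foreign, pair))
    if fusions is not None:
        out["gene_fusion"] = float(gene_fusion_flag(fusions, pair))
    return out
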