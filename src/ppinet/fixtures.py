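"""Planted-truth synthetic universe for end-to-end testing and calibration.

The generator emulates the statistical structure the classifier assumes:
a set of *planted* true interactions whose members are enriched for every
evidence channel, embedded in a background of independent signals.

* expression: each planted pair shares a latent expression factor so its
  log-RPKM profiles correlate at about ``rho_true`` (diluted for genes in
  several pairs); counts are Poisson draws at realistic depth;
* GO: genes carry random leaf terms of a three-level toy ontology; a
  planted pair additionally shares a specific leaf with probability
  ``go_boost``, pulling its lowest common class down the DAG;
* phylogenetic profiles: random presence/absence over a genome panel;
  a ``profile_match`` fraction of planted pairs get nearly identical
  profiles;
* interologs / gene fusion: a configured fraction of planted pairs gets
  supporting evidence; a small background rate plants false support on
  random pairs (drawn label-blind, so zeroed dials leave no signal);
* structures: a fraction of planted pairs receives a two-helix dimer
  template plus query chains that are noisy rigid copies of its chains.

Regeneration with the same config is byte-identical; every written file
parses back through :mod:`ppinet.io`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .genomic import (
    ExpressionMatrix,
    ForeignInteractionSet,
    FusionHitSet,
    GoAnnotationSet,
    ORGANISMS,
    OrthologMap,
    coexpression_matrix,
    phylo_profile_matrix,
    rpkm,
)
from .features import FEATURE_NAMES, empty_feature_table
from .model import sample_negatives
from .pairs import GoldStandardSet, Pair, PathwayCoreSet
from .structural import (
    Alignment,
    ComplexTemplate,
    StructuralFeatureSet,
    StructureChain,
    best_template_features,
    extract_interface,
    identity_alignment,
)

logger = logging.getLogger(__name__)

PATHWAY_NAMES = ("GA", "IAA", "CK", "ET", "ABA")
SOURCE_DATABASES = ("BioGRID", "IntAct", "DIP", "MINT", "BIND")


@dataclass
class FixtureConfig:
    """Dials of the synthetic universe; defaults are the study conditions."""

    n_genes: int = 300
    n_planted_pairs: int = 400
    n_samples: int = 50
    n_genomes: int = 30
    rho_true: float = 0.7
    go_boost: float = 0.7
    profile_match: float = 0.5
    interolog_coverage: float = 0.4
    interolog_false_rate: float = 0.01
    fusion_coverage: float = 0.3
    fusion_false_rate: float = 0.005
    structural_coverage: float = 0.5
    negative_pool_size: int = 32000
    n_pathways: int = 5
    cores_per_pathway: int = 12
    seed: int = 17

    def __post_init__(self) -> None:
        for name in (
            "rho_true", "go_boost", "profile_match", "interolog_coverage",
            "interolog_false_rate", "fusion_coverage", "fusion_false_rate",
            "structural_coverage",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        max_pairs = self.n_genes * (self.n_genes - 1) // 2
        if self.n_planted_pairs > max_pairs:
            raise ValueError("more planted pairs than gene pairs exist")
        if self.n_planted_pairs + self.negative_pool_size > max_pairs:
            raise ValueError("negative pool exceeds the non-planted pair universe")

    def null_signal(self) -> "FixtureConfig":
        """A copy with every signal dial at zero (label-blind features)."""
        return FixtureConfig(
            **{
                **asdict(self),
                "rho_true": 0.0,
                "go_boost": 0.0,
                "profile_match": 0.0,
                "interolog_coverage": 0.0,
                "fusion_coverage": 0.0,
                "structural_coverage": 0.0,
            }
        )


@dataclass
class FixtureBundle:
    """In-memory fixture universe plus (optionally) its on-disk files."""

    config: FixtureConfig
    genes: list[str]
    gold: GoldStandardSet
    negative_pool: list[Pair]
    expression: ExpressionMatrix
    annotations: GoAnnotationSet
    profiles: pd.DataFrame
    orthologs: OrthologMap
    foreign: ForeignInteractionSet
    fusions: FusionHitSet
    structural: dict[Pair, StructuralFeatureSet]
    pathways: list[PathwayCoreSet]
    files: dict[str, Path] = field(default_factory=dict)

    @property
    def planted_pairs(self) -> list[Pair]:
        return sorted(self.gold.positives)

    def feature_table(self, pairs: list[Pair] | None = None) -> pd.DataFrame:
        """Assemble the 11-feature table for the given pairs (vectorised)."""
        if pairs is None:
            pairs = self.planted_pairs + self.negative_pool
        table = empty_feature_table(pairs)
        gene_idx = {g: i for i, g in enumerate(self.genes)}
        ia = np.array([gene_idx[a] for a, _ in pairs])
        ib = np.array([gene_idx[b] for _, b in pairs])

        coexpr = coexpression_matrix(self.expression).to_numpy()
        table["coexpression_pcc"] = coexpr[ia, ib]
        profile_corr = phylo_profile_matrix(self.profiles).to_numpy()
        table["phylo_profile_sim"] = profile_corr[ia, ib]

        N = self.annotations.n_genes()
        log2N = np.log(2.0 / N)
        for aspect, column in (("BP", "go_bp_sim"), ("MF", "go_mf_sim"), ("CC", "go_cc_sim")):
            closed = self.annotations.closed_terms(aspect)
            counts = self.annotations.term_counts(aspect)
            values = np.full(len(pairs), np.nan)
            for row, (a, b) in enumerate(pairs):
                ta, tb = closed.get(a), closed.get(b)
                if not ta or not tb:
                    continue
                common = ta & tb
                if not common:
                    continue
                n = max(min(counts[t] for t in common), 2)
                values[row] = 0.0 if n >= N else np.log(n / N) / log2N
            table[column] = values

        support = _interolog_pair_support(self.orthologs, self.foreign)
        table["interolog_support"] = [float(support.get(p, 0)) for p in pairs]
        fused = _fusion_pairs(self.fusions)
        table["gene_fusion"] = [1.0 if p in fused else 0.0 for p in pairs]

        for name in ("tm_score", "rmsd", "preserved_interface_size", "preserved_fraction"):
            table[name] = [
                getattr(self.structural[p], name) if p in self.structural else np.nan
                for p in pairs
            ]
        return table[list(FEATURE_NAMES)]


def _interolog_pair_support(orth: OrthologMap, foreign: ForeignInteractionSet) -> dict[Pair, int]:
    """pair -> organism support count, by inverting the ortholog maps."""
    support: dict[Pair, int] = {}
    for organism, mapping in orth.groups.items():
        by_group: dict[str, list[str]] = {}
        for gene, group in mapping.items():
            by_group.setdefault(group, []).append(gene)
        for ga, gb in foreign.interactions.get(organism, ()):
            for a in by_group.get(ga, ()):
                for b in by_group.get(gb, ()):
                    if a == b:
                        continue
                    pair = (a, b) if a <= b else (b, a)
                    support[pair] = support.get(pair, 0) + 1
    return support


def _fusion_pairs(fusions: FusionHitSet) -> set[Pair]:
    """Pairs with Rosetta-stone evidence, via the per-pair fusion rule."""
    from .genomic import gene_fusion_flag

    out: set[Pair] = set()
    for per_gene in fusions.hits.values():
        genes = sorted(per_gene)
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                pair = (a, b)
                if pair not in out and gene_fusion_flag(fusions, pair):
                    out.add(pair)
    return out


# ---------------------------------------------------------------------------
# toy structures


def alpha_helix(
    length: int, *, rise: float = 1.5, radius: float = 2.3, turn_deg: float = 100.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Idealised alpha-helical CA trace along the x axis."""
    t = np.arange(length)
    angle = np.deg2rad(turn_deg) * t + phase
    return np.column_stack([rise * t, radius * np.cos(angle), radius * np.sin(angle)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_toy_complex(
    length_a: int = 30,
    length_b: int = 30,
    *,
    separation: float = 5.5,
    noise: float = 0.0,
    truncate: tuple[int, int] = (0, 0),
    seed: int = 0,
) -> tuple[ComplexTemplate, StructureChain, StructureChain, Alignment, Alignment]:
    """A two-helix dimer template plus noisy rigid-copy query chains.

    The template is two parallel helices ``separation`` Å apart (must
    yield a non-empty 6.05 Å interface); each query chain is the matching
    template chain under a random rigid motion plus isotropic Gaussian
    noise with per-atom RMS displacement ``noise`` (Å), optionally
    truncated at the C terminus.  The returned alignments are
    sequence-index identities over the query residues.
    """
    if min(length_a, length_b) < 16:
        raise ValueError("toy chains must have >= 16 residues (standard d0 regime)")
    rng = np.random.default_rng(seed)
    # antiphase parallel helices: facing CA atoms approach to ~separation
    coords1 = alpha_helix(length_a)
    coords2 = alpha_helix(length_b, phase=np.pi) + np.array([0.0, separation + 4.6, 0.0])

    def chain(cid: str, coords: np.ndarray) -> StructureChain:
        return StructureChain(
            chain_id=cid,
            residue_ids=[(i + 1, "") for i in range(len(coords))],
            ca_coords=coords,
            atom_coords=[c[None, :] for c in coords],
        )

    template = ComplexTemplate.from_chains("toy", chain("A", coords1), chain("B", coords2))
    if len(template.interface) == 0:
        raise ValueError(f"separation {separation} Å yields an empty interface")

    def query(cid: str, coords: np.ndarray, cut: int) -> StructureChain:
        kept = coords[: len(coords) - cut] if cut else coords
        moved = kept @ _random_rotation(rng).T + rng.normal(scale=50.0, size=3)
        if noise > 0:
            moved = moved + rng.normal(scale=noise / np.sqrt(3.0), size=moved.shape)
        return chain(cid, moved)

    qa = query("A", coords1, truncate[0])
    qb = query("B", coords2, truncate[1])
    return template, qa, qb, identity_alignment(len(qa)), identity_alignment(len(qb))


# ---------------------------------------------------------------------------
# generation


def generate_fixture(config: FixtureConfig, outdir: str | Path | None = None) -> FixtureBundle:
    """Generate the full synthetic universe; write files when ``outdir`` given."""
    rng = np.random.default_rng(config.seed)
    genes = [f"AT{1 + i % 5}G{(i + 1) * 10:05d}" for i in range(config.n_genes)]

    # --- planted interactions + source tags
    all_pair_count = config.n_genes * (config.n_genes - 1) // 2
    chosen = rng.choice(all_pair_count, size=config.n_planted_pairs, replace=False)
    chosen.sort()
    planted: list[Pair] = []
    # unrank the linear index into (i, j) with i < j
    starts = np.cumsum([0] + [config.n_genes - 1 - i for i in range(config.n_genes - 1)])
    for linear in chosen:
        i = int(np.searchsorted(starts, linear, side="right")) - 1
        j = i + 1 + int(linear - starts[i])
        a, b = genes[i], genes[j]
        planted.append((a, b) if a <= b else (b, a))
    gold = GoldStandardSet(snapshot_date="synthetic")
    db_probs = np.array([0.5, 0.3, 0.1, 0.05, 0.05])
    for pair in planted:
        first = SOURCE_DATABASES[rng.choice(5, p=db_probs)]
        gold.add(*pair, source=first)
        if rng.random() < 0.3:
            gold.add(*pair, source=SOURCE_DATABASES[int(rng.integers(0, 5))])
    planted_set = set(planted)

    negatives = sorted(
        sample_negatives(genes, planted_set, config.negative_pool_size, int(rng.integers(2**31)))
    )

    # --- expression: Gaussian sample with target correlation rho on every
    # planted edge.  I + rho*A is projected to the nearest valid correlation
    # matrix (eigenvalue clipping), so hub genes get proportionally shrunk
    # correlations instead of an invalid target.
    gene_idx = {g: i for i, g in enumerate(genes)}
    noise = rng.normal(size=(config.n_genes, config.n_samples))
    rho = config.rho_true
    if rho == 0:
        profile_z = noise
    else:
        adjacency = np.zeros((config.n_genes, config.n_genes))
        for a, b in planted:
            adjacency[gene_idx[a], gene_idx[b]] = adjacency[gene_idx[b], gene_idx[a]] = 1.0
        target = np.eye(config.n_genes) + rho * adjacency
        eigval, eigvec = np.linalg.eigh(target)
        projected = (eigvec * np.clip(eigval, 1e-3, None)) @ eigvec.T
        scale = np.sqrt(np.diag(projected))
        projected /= np.outer(scale, scale)
        chol = np.linalg.cholesky(projected + 1e-9 * np.eye(config.n_genes))
        profile_z = chol @ noise
    mean_log = rng.normal(loc=np.log(30.0), scale=1.0, size=config.n_genes)
    lengths = pd.Series(rng.integers(500, 3000, size=config.n_genes), index=genes, dtype=float)
    depth = 2e7
    target_rpkm = np.exp(mean_log[:, None] + profile_z)
    lam = target_rpkm * lengths.to_numpy()[:, None] * depth / 1e9
    counts = pd.DataFrame(
        rng.poisson(lam),
        index=genes,
        columns=[f"S{i + 1:03d}" for i in range(config.n_samples)],
    )
    expression = rpkm(counts, lengths)

    # --- GO toy ontologies
    parents: dict[str, set[str]] = {}
    direct: dict[str, dict[str, set[str]]] = {}
    n_mid, n_leaf = 10, 60
    for aspect in ("BP", "MF", "CC"):
        root = f"{aspect}:ROOT"
        mids = [f"{aspect}:M{i + 1:02d}" for i in range(n_mid)]
        leaves = [f"{aspect}:L{i + 1:03d}" for i in range(n_leaf)]
        parents.setdefault(root, set())
        for m in mids:
            parents.setdefault(m, set()).add(root)
        for i, leaf in enumerate(leaves):
            parents.setdefault(leaf, set()).add(mids[i % n_mid])
        annot: dict[str, set[str]] = {}
        for gene in genes:
            k = int(rng.integers(1, 4))
            annot[gene] = {leaves[int(t)] for t in rng.choice(n_leaf, size=k, replace=False)}
        for a, b in planted:
            if rng.random() < config.go_boost:
                shared = leaves[int(rng.integers(0, n_leaf))]
                annot[a].add(shared)
                annot[b].add(shared)
        direct[aspect] = annot
    annotations = GoAnnotationSet(direct=direct, parents=parents, genome_size=config.n_genes)

    # --- phylogenetic profiles
    profiles = pd.DataFrame(
        rng.integers(0, 2, size=(config.n_genes, config.n_genomes)),
        index=genes,
        columns=[f"genome{i + 1:03d}" for i in range(config.n_genomes)],
    )
    for a, b in planted:
        if rng.random() < config.profile_match:
            copied = profiles.loc[a].to_numpy().copy()
            flips = rng.choice(config.n_genomes, size=2, replace=False)
            copied[flips] = 1 - copied[flips]
            profiles.loc[b] = copied

    # --- orthologs, interologs
    groups: dict[str, dict[str, str]] = {org: {} for org in ORGANISMS}
    foreign_sets: dict[str, set[tuple[str, str]]] = {org: set() for org in ORGANISMS}
    for org in ORGANISMS:
        has_orth = rng.random(config.n_genes) < 0.6
        for g, gene in enumerate(genes):
            if has_orth[g]:
                groups[org][gene] = f"{org}_G{g:04d}"

    def plant_support(pair: Pair, n_orgs: int) -> None:
        orgs = [ORGANISMS[int(i)] for i in rng.choice(len(ORGANISMS), size=n_orgs, replace=False)]
        for org in orgs:
            for gene in pair:
                groups[org].setdefault(gene, f"{org}_G{gene_idx[gene]:04d}")
            ga, gb = groups[org][pair[0]], groups[org][pair[1]]
            key = (ga, gb) if ga <= gb else (gb, ga)
            foreign_sets[org].add(key)

    for pair in planted:
        if rng.random() < config.interolog_coverage:
            plant_support(pair, int(rng.integers(1, 4)))
    # label-blind background support on random candidate pairs
    n_false = int(round(config.interolog_false_rate * config.negative_pool_size))
    universe = planted + negatives
    for idx in rng.choice(len(universe), size=min(n_false, len(universe)), replace=False):
        plant_support(universe[int(idx)], 1)
    orthologs = OrthologMap(groups=groups)
    foreign = ForeignInteractionSet(interactions=foreign_sets)

    # --- gene fusion
    hits: dict[str, dict[str, list[tuple[int, int, float]]]] = {}
    counter = 0

    def plant_fusion(pair: Pair) -> None:
        nonlocal counter
        protein = f"FUSED{counter:04d}"
        counter += 1
        hits[protein] = {
            pair[0]: [(1, 180, 1e-10)],
            pair[1]: [(220, 400, 1e-10)],
        }

    for pair in planted:
        if rng.random() < config.fusion_coverage:
            plant_fusion(pair)
    n_false_fusion = int(round(config.fusion_false_rate * config.negative_pool_size))
    for idx in rng.choice(len(universe), size=min(n_false_fusion, len(universe)), replace=False):
        plant_fusion(universe[int(idx)])
    fusions = FusionHitSet(hits=hits)

    # --- structural templates for a fraction of planted pairs
    structural: dict[Pair, StructuralFeatureSet] = {}
    for pair in planted:
        if rng.random() >= config.structural_coverage:
            continue
        template, qa, qb, aln_a, aln_b = generate_toy_complex(
            30, 30,
            noise=0.3,
            truncate=(int(rng.integers(0, 5)), int(rng.integers(0, 5))),
            seed=int(rng.integers(2**31)),
        )
        feats = best_template_features(qa, qb, [(template, aln_a, aln_b)])
        if feats is not None:
            structural[pair] = feats

    # --- pathway cores from the planted-pair gene pool
    planted_genes = sorted({g for p in planted for g in p})
    pathways = []
    for name in PATHWAY_NAMES[: config.n_pathways]:
        take = rng.choice(len(planted_genes), size=min(config.cores_per_pathway, len(planted_genes)), replace=False)
        pathways.append(PathwayCoreSet(name=name, cores={planted_genes[int(i)] for i in take}))

    bundle = FixtureBundle(
        config=config,
        genes=genes,
        gold=gold,
        negative_pool=negatives,
        expression=expression,
        annotations=annotations,
        profiles=profiles,
        orthologs=orthologs,
        foreign=foreign,
        fusions=fusions,
        structural=structural,
        pathways=pathways,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: FixtureBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["gold_standard"] = outdir / "gold_standard.tsv"
    pio.write_ppi_table(bundle.gold, files["gold_standard"])
    files["negative_pool"] = outdir / "negative_pool.tsv"
    pio.write_ppi_table(set(bundle.negative_pool), files["negative_pool"])
    files["expression"] = outdir / "expression_counts.tsv"
    pio.write_expression_counts(bundle.expression.counts, bundle.expression.lengths, files["expression"])

    files["go_annotations"] = outdir / "go_annotations.tsv"
    lines = []
    for aspect in ("BP", "MF", "CC"):
        for gene in sorted(bundle.annotations.direct[aspect]):
            for term in sorted(bundle.annotations.direct[aspect][gene]):
                lines.append(f"{gene}\t{aspect}\t{term}")
    files["go_annotations"].write_text("\n".join(lines) + "\n")

    files["go_hierarchy"] = outdir / "go_hierarchy.tsv"
    lines = [
        f"{child}\t{parent}"
        for child in sorted(bundle.annotations.parents)
        for parent in sorted(bundle.annotations.parents[child])
    ]
    files["go_hierarchy"].write_text("\n".join(lines) + "\n")

    files["phylo_profiles"] = outdir / "phylo_profiles.tsv"
    out = bundle.profiles.copy()
    out.index.name = "gene"
    out.to_csv(files["phylo_profiles"], sep="\t")

    files["orthologs"] = outdir / "orthologs.tsv"
    lines = [
        f"{org}\t{gene}\t{group}"
        for org in sorted(bundle.orthologs.groups)
        for gene, group in sorted(bundle.orthologs.groups[org].items())
    ]
    files["orthologs"].write_text("\n".join(lines) + "\n")

    files["foreign_interactions"] = outdir / "foreign_interactions.tsv"
    lines = [
        f"{org}\t{a}\t{b}"
        for org in sorted(bundle.foreign.interactions)
        for a, b in sorted(bundle.foreign.interactions[org])
    ]
    files["foreign_interactions"].write_text("\n".join(lines) + "\n")

    files["fusion_hits"] = outdir / "fusion_hits.tsv"
    lines = [
        f"{protein}\t{gene}\t{start}\t{end}\t{evalue:g}"
        for protein in sorted(bundle.fusions.hits)
        for gene in sorted(bundle.fusions.hits[protein])
        for start, end, evalue in bundle.fusions.hits[protein][gene]
    ]
    files["fusion_hits"].write_text("\n".join(lines) + "\n")

    for pathway in bundle.pathways:
        key = f"pathway_{pathway.name}"
        files[key] = outdir / f"{pathway.name}.cores.tsv"
        files[key].write_text("\n".join(sorted(pathway.cores)) + "\n")

    manifest = {
        "config": asdict(bundle.config),
        "checksums": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(files.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = manifest_path
    bundle.files = files


def random_network(n_nodes: int = 100, n_edges: int = 300, seed: int = 0):
    """A G(n, m) random interactome used as a null-model test bed."""
    import networkx as nx

    from .network import InteractionNetwork

    graph = nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    relabel = {i: f"AT1G{(i + 1) * 10:05d}" for i in graph.nodes}
    return InteractionNetwork(nx.relabel_nodes(graph, relabel))
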