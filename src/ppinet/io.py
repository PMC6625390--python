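"""Readers and writers for the tabular and structural files the pipeline touches.

All tabular formats are plain TSV so that fixtures and outputs diff cleanly:

* pair tables: two identifier columns, optional third ``source`` column;
* expression counts: ``gene  length  <sample...>`` with integer counts;
* GO annotations: ``gene  aspect  term`` with aspect in {BP, MF, CC};
* GO hierarchy: ``child  parent`` edges (is_a/part_of collapsed);
* SIF edge lists: ``a  interaction-type  b``.

Structures are read from PDB files through Biopython; for each residue the
highest-occupancy alternate location is kept.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .pairs import GoldStandardSet, Pair, PathwayCoreSet, canonical_id, canonical_pair

logger = logging.getLogger(__name__)

GO_ASPECTS = ("BP", "MF", "CC")


class FormatError(ValueError):
    """A file violated the expected dialect; the message names the location."""


# ---------------------------------------------------------------------------
# pair tables


def read_ppi_table(
    path: str | Path,
    *,
    source_column: bool | None = None,
    snapshot_date: str | None = None,
) -> GoldStandardSet:
    """Read a two/three-column TSV of interacting pairs into a canonical set.

    Pairs are canonicalized (uppercase, isoform-stripped, sorted) and
    de-duplicated; duplicates and rejected self-pairs are logged.
    ``source_column=None`` auto-detects a third column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gold = GoldStandardSet(snapshot_date=snapshot_date)
    n_rows = n_dup = n_self = 0
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}")
            has_source = source_column if source_column is not None else len(fields) >= 3
            source = fields[2] if has_source and len(fields) >= 3 else None
            n_rows += 1
            try:
                pair = canonical_pair(fields[0], fields[1])
            except ValueError:
                n_self += 1
                logger.warning("%s:%d: self-pair %r skipped", path, lineno, fields[0])
                continue
            if pair in gold.positives and (source is None or source in gold.sources.get(pair, ())):
                n_dup += 1
            gold.add(fields[0], fields[1], source)
    if n_rows == 0:
        raise FormatError(f"{path}: no pair rows")
    if n_dup:
        logger.info("%s: %d duplicate pair rows collapsed", path, n_dup)
    if n_self:
        logger.info("%s: %d self-pairs rejected", path, n_self)
    return gold


def write_ppi_table(pairs: set[Pair] | GoldStandardSet, path: str | Path) -> None:
    """Write canonical pairs, one per line, deterministically sorted."""
    if isinstance(pairs, GoldStandardSet):
        rows = sorted(
            (a, b, ",".join(sorted(pairs.sources.get((a, b), ())))) for a, b in pairs.positives
        )
        lines = ["\t".join(r).rstrip("\t") for r in rows]
    else:
        lines = ["\t".join(p) for p in sorted(pairs)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression counts


def read_expression_counts(path: str | Path) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Read a ``gene length sample...`` count table.

    Returns ``(counts, lengths, totals)`` where ``counts`` is genes x samples,
    ``lengths`` is the transcript length in bp and ``totals`` the per-sample
    mapped-read column sums.  Genes with a missing/zero length are dropped
    with a warning; negative or non-numeric counts are errors.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in table.columns:
        raise FormatError(f"{path}: missing required 'length' column")
    lengths = pd.to_numeric(table["length"], errors="coerce")
    counts = table.drop(columns=["length"])
    for col in counts.columns:
        coerced = pd.to_numeric(counts[col], errors="coerce")
        bad = coerced.isna() & counts[col].notna()
        if bad.any():
            gene = bad.idxmax()
            raise FormatError(f"{path}: non-numeric count at gene {gene!r}, sample {col!r}")
        counts[col] = coerced
    if (counts.to_numpy() < 0).any():
        locs = np.argwhere(counts.to_numpy() < 0)[0]
        raise FormatError(
            f"{path}: negative count at gene {counts.index[locs[0]]!r}, "
            f"sample {counts.columns[locs[1]]!r}"
        )
    missing_len = lengths.isna() | (lengths <= 0)
    if missing_len.any():
        dropped = list(lengths.index[missing_len])
        logger.warning("%s: dropping %d genes with missing length: %s", path, len(dropped), dropped[:5])
        counts = counts.loc[~missing_len]
        lengths = lengths[~missing_len]
    counts.index = [canonical_id(g) for g in counts.index]
    lengths.index = counts.index
    totals = counts.sum(axis=0)
    return counts, lengths.astype(float), totals.astype(float)


def write_expression_counts(
    counts: pd.DataFrame, lengths: pd.Series, path: str | Path
) -> None:
    out = counts.copy()
    out.insert(0, "length", lengths.astype(int))
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# structures


def read_structures(path: str | Path, *, model_index: int = 0) -> dict[str, "StructureChain"]:
    """Parse the chains of a PDB file into :class:`~ppinet.structural.StructureChain`.

    For residues with alternate locations, the highest-occupancy conformer is
    kept (ties: first in file order).  Raises :class:`FormatError` if the file
    contains no ATOM records.
    """
    from .structural import StructureChain  # deferred: avoid import cycle

    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise FormatError(f"{path}: no ATOM records")
    chains: dict[str, StructureChain] = {}
    for chain in models[model_index]:
        residue_ids: list[tuple[int, str]] = []
        ca: list[np.ndarray] = []
        atoms_per_res: list[np.ndarray] = []
        for residue in chain:
            if residue.id[0] != " ":  # skip HETATM/water
                continue
            coords = []
            ca_coord = None
            for atom in residue:
                if atom.is_disordered():
                    # Biopython exposes the highest-occupancy altloc as the
                    # selected child; ties resolve to file order.
                    atom = atom.selected_child
                coords.append(atom.coord)
                if atom.get_name() == "CA":
                    ca_coord = atom.coord
            if not coords:
                continue
            if ca_coord is None:
                ca_coord = np.mean(coords, axis=0)
            residue_ids.append((residue.id[1], residue.id[2].strip()))
            ca.append(np.asarray(ca_coord, dtype=float))
            atoms_per_res.append(np.asarray(coords, dtype=float))
        if residue_ids:
            chains[chain.id] = StructureChain(
                chain_id=chain.id,
                residue_ids=residue_ids,
                ca_coords=np.vstack(ca),
                atom_coords=atoms_per_res,
            )
    if not chains:
        raise FormatError(f"{path}: no ATOM records")
    return chains


def write_pdb(chains: dict[str, np.ndarray], path: str | Path, *, atom_name: str = "CA") -> None:
    """Write single-atom-per-residue chains (id -> N x 3 coords) as a minimal PDB."""
    lines = []
    serial = 1
    for chain_id in sorted(chains):
        coords = np.asarray(chains[chain_id], dtype=float)
        for i, (x, y, z) in enumerate(coords, start=1):
            lines.append(
                f"ATOM  {serial:5d} {atom_name:^4s} ALA {chain_id}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# networks


def write_network_edgelist(
    network, path: str | Path, *, fmt: str = "tsv", interaction_type: str = "pp"
) -> None:
    """Write an interaction network as a sorted TSV edge list or Cytoscape SIF."""
    edges = sorted(canonical_pair(a, b) for a, b in network.edges())
    if not edges:
        raise ValueError("refusing to write an empty network")
    if fmt == "sif":
        lines = [f"{a}\t{interaction_type}\t{b}" for a, b in edges]
    elif fmt == "tsv":
        lines = [f"{a}\t{b}" for a, b in edges]
    else:
        raise ValueError(f"unknown edge-list format {fmt!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network_edgelist(path: str | Path):
    """Read a TSV or SIF edge list into an undirected networkx graph."""
    import networkx as nx

    graph = nx.Graph()
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 3:  # SIF: a type b
            a, _, b = fields
        elif len(fields) == 2:
            a, b = fields
        else:
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns")
        graph.add_edge(*canonical_pair(a, b))
    return graph


# ---------------------------------------------------------------------------
# GO annotation + hierarchy


def read_go_annotations(path: str | Path) -> dict[str, dict[str, set[str]]]:
    """Read ``gene aspect term`` rows into aspect -> gene -> direct terms."""
    annotations: dict[str, dict[str, set[str]]] = {a: {} for a in GO_ASPECTS}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns (gene, aspect, term)")
        gene, aspect, term = fields
        if aspect not in GO_ASPECTS:
            raise FormatError(f"{path}:{lineno}: unknown aspect {aspect!r}")
        annotations[aspect].setdefault(canonical_id(gene), set()).add(term)
    return annotations


def read_go_hierarchy(path: str | Path) -> dict[str, set[str]]:
    """Read ``child parent`` edges into child -> parents."""
    parents: dict[str, set[str]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns (child, parent)")
        child, parent = fields
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    return parents


# ---------------------------------------------------------------------------
# misc tables


def read_pathway_cores(path: str | Path) -> PathwayCoreSet:
    """Read a one-identifier-per-line core-protein list; name from the stem."""
    path = Path(path)
    cores = {
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return PathwayCoreSet(name=path.stem, cores=cores)


def read_phylo_profiles(path: str | Path) -> pd.DataFrame:
    """Read a gene x genome 0/1 presence table."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    values = table.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: presence/absence entries must be 0/1")
    table.index = [canonical_id(g) for g in table.index]
    return table.astype(int)


def read_ortholog_map(path: str | Path):
    """Read ``organism gene group`` rows into an :class:`OrthologMap`."""
    from .genomic import OrthologMap

    groups: dict[str, dict[str, str]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns (organism, gene, group)")
        organism, gene, group = fields
        groups.setdefault(organism, {})[canonical_id(gene)] = group
    return OrthologMap(groups=groups)


def read_foreign_interactions(path: str | Path):
    """Read ``organism group_a group_b`` rows into a :class:`ForeignInteractionSet`."""
    from .genomic import ForeignInteractionSet

    interactions: dict[str, set[tuple[str, str]]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns (organism, group, group)")
        organism, ga, gb = fields
        key = (ga, gb) if ga <= gb else (gb, ga)
        interactions.setdefault(organism, set()).add(key)
    return ForeignInteractionSet(interactions=interactions)


def read_fusion_hits(path: str | Path):
    """Read ``foreign_protein gene start end evalue`` rows into a :class:`FusionHitSet`."""
    from .genomic import FusionHitSet

    hits: dict[str, dict[str, list[tuple[int, int, float]]]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(
                f"{path}:{lineno}: expected 5 columns (protein, gene, start, end, evalue)"
            )
        protein, gene, start, end, evalue = fields
        hits.setdefault(protein, {}).setdefault(canonical_id(gene), []).append(
            (int(start), int(end), float(evalue))
        )
    return FusionHitSet(hits=hits)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a per-pair feature TSV (index: protein_a, protein_b)."""
    return pd.read_csv(path, sep="\t", index_col=[0, 1])


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.sort_index().to_csv(path, sep="\t", float_format="%.6g")


def validate_file(path: str | Path) -> str:
    """Best-effort dialect sniffing used by ``ppinet io validate``."""
    path = Path(path)
    head = path.read_text().splitlines()[:5]
    if head and head[0].startswith(("ATOM", "HEADER", "MODEL")):
        read_structures(path)
        return "pdb"
    first = head[0].split("\t") if head else []
    if "length" in first:
        read_expression_counts(path)
        return "expression"
    if len(first) == 3 and first[1] in GO_ASPECTS:
        read_go_annotations(path)
        return "go-annotations"
    if len(first) in (2, 3):
        read_ppi_table(path)
        return "pairs"
    raise FormatError(f"{path}: unrecognized format")
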