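"""Template-based structural interaction features.

A candidate pair is scored against a library of template complexes (dimers
with a known chain-chain interface).  Each query model is rigidly
superposed (Kabsch) onto one template chain; alignments with TM-score >=
0.4 on both chains yield an interaction model, from which four features
are read off:

* ``tm_score``     — min of the two chain TM-scores (structural similarity)
* ``rmsd``         — max of the two superposition RMSDs (structural distance)
* ``preserved_interface_size``     — template interface contacts covered by
  both alignments
* ``preserved_fraction``           — preserved / template interface size

Interfaces are defined by an interatomic distance cutoff of 6.05 Å between
chains, the PIBASE convention.  TM-score uses the standard normalization
d0 = 1.24 * (L - 15)^(1/3) - 1.8 for L >= 16 and a fallback d0 = 0.5 for
shorter chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

logger = logging.getLogger(__name__)

INTERFACE_CUTOFF = 6.05  # Å, interatomic
TM_SCORE_CUTOFF = 0.4
RMSD_DOMAIN_MAX = 20.0  # Å, imputation ceiling for template-absent pairs

# alignment: query residue index -> target residue index
Alignment = dict[int, int]


@dataclass
class StructureChain:
    """One protein chain: CA trace for superposition, all atoms for contacts."""

    chain_id: str
    residue_ids: list[tuple[int, str]]
    ca_coords: np.ndarray  # (L, 3)
    atom_coords: list[np.ndarray] | None = None  # per-residue (n_atoms, 3)

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if not np.isfinite(self.ca_coords).all():
            raise ValueError(f"chain {self.chain_id}: non-finite coordinates")

    def __len__(self) -> int:
        return self.ca_coords.shape[0]

    def all_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """(atoms, residue index per atom); falls back to the CA trace."""
        if self.atom_coords is None:
            return self.ca_coords, np.arange(len(self))
        atoms = np.vstack(self.atom_coords)
        labels = np.concatenate(
            [np.full(len(res), i) for i, res in enumerate(self.atom_coords)]
        )
        return atoms, labels


@dataclass
class InterfaceContactSet:
    """Cross-chain residue contacts of a template dimer."""

    contacts: set[tuple[int, int]]  # residue indices (chain1, chain2)
    cutoff: float = INTERFACE_CUTOFF

    def __len__(self) -> int:
        return len(self.contacts)

    def interface_residues(self) -> tuple[set[int], set[int]]:
        return {i for i, _ in self.contacts}, {j for _, j in self.contacts}


@dataclass
class ComplexTemplate:
    """A template dimer with its extracted interface."""

    template_id: str
    chain1: StructureChain
    chain2: StructureChain
    interface: InterfaceContactSet

    @classmethod
    def from_chains(
        cls, template_id: str, chain1: StructureChain, chain2: StructureChain,
        cutoff: float = INTERFACE_CUTOFF,
    ) -> "ComplexTemplate":
        return cls(template_id, chain1, chain2, extract_interface(chain1, chain2, cutoff))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    aligned_length: int
    distances: np.ndarray  # per aligned residue pair after superposition


@dataclass
class StructuralFeatureSet:
    tm_score: float
    rmsd: float
    preserved_interface_size: int
    preserved_fraction: float
    template_id: str | None = None


STRUCTURAL_FEATURES = ("tm_score", "rmsd", "preserved_interface_size", "preserved_fraction")


# ---------------------------------------------------------------------------


def extract_interface(
    chain1: StructureChain, chain2: StructureChain, cutoff: float = INTERFACE_CUTOFF
) -> InterfaceContactSet:
    """All residue pairs with any interatomic distance <= cutoff.

    Symmetric under chain swap up to index transposition.
    """
    if len(chain1) == 0 or len(chain2) == 0:
        raise ValueError("cannot extract an interface from an empty chain")
    atoms1, labels1 = chain1.all_atoms()
    atoms2, labels2 = chain2.all_atoms()
    diff = atoms1[:, None, :] - atoms2[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    contacts = {
        (int(labels1[i]), int(labels2[j]))
        for i, j in zip(*np.nonzero(dist <= cutoff))
    }
    return InterfaceContactSet(contacts=contacts, cutoff=cutoff)


def kabsch_superpose(
    query: StructureChain, target: StructureChain, mapping: Alignment
) -> SuperpositionResult:
    """Least-squares rigid superposition of mapped CA pairs (Kabsch/SVD).

    ``mapping`` sends query residue indices to target residue indices and
    must contain at least 3 pairs of non-collinear points.
    """
    if len(mapping) < 3:
        raise ValueError("superposition needs at least 3 aligned residue pairs")
    q_idx = np.fromiter(mapping.keys(), dtype=int)
    t_idx = np.fromiter((mapping[i] for i in q_idx), dtype=int)
    x = query.ca_coords[q_idx]
    y = target.ca_coords[t_idx]
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("aligned coordinates are collinear; rotation is degenerate")
    sup = SVDSuperimposer()
    sup.set(y, x)  # superimpose x (query) onto y (target)
    sup.run()
    rot, tran = sup.get_rotran()
    transformed = x @ rot + tran
    distances = np.sqrt(((transformed - y) ** 2).sum(axis=1))
    return SuperpositionResult(
        rotation=rot,
        translation=tran,
        rmsd=float(sup.get_rms()),
        aligned_length=len(mapping),
        distances=distances,
    )


def tm_score_d0(l_norm: int) -> float:
    """Standard TM-score distance scale; fallback 0.5 Å below the L=16 regime."""
    if l_norm < 16:
        logger.info("TM-score normalization length %d < 16; using d0 = 0.5", l_norm)
        return 0.5
    return 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8


def tm_score(
    superposition: SuperpositionResult, l_norm: int | None = None, *, query_length: int | None = None
) -> float:
    """TM = (1/L_norm) * sum over aligned pairs of 1 / (1 + (d_i/d0)^2).

    Normalized by the query model length by default (``l_norm`` overrides).
    """
    if l_norm is None:
        l_norm = query_length if query_length is not None else superposition.aligned_length
    d0 = tm_score_d0(l_norm)
    terms = 1.0 / (1.0 + (superposition.distances / d0) ** 2)
    return float(terms.sum() / l_norm)


def build_interaction_model(
    model_a: StructureChain,
    model_b: StructureChain,
    template: ComplexTemplate,
    alignment_a: Alignment,
    alignment_b: Alignment,
    *,
    tm_cutoff: float = TM_SCORE_CUTOFF,
) -> StructuralFeatureSet | None:
    """Superpose the two query models onto the template chains and score.

    Returns None (rejection) when either chain superposition falls below
    the TM-score cutoff: the template gives no usable interaction model.
    """
    if len(template.interface) == 0:
        raise ValueError(f"template {template.template_id} has an empty interface")
    sup_a = kabsch_superpose(model_a, template.chain1, alignment_a)
    sup_b = kabsch_superpose(model_b, template.chain2, alignment_b)
    tm_a = tm_score(sup_a, query_length=len(model_a))
    tm_b = tm_score(sup_b, query_length=len(model_b))
    if tm_a < tm_cutoff or tm_b < tm_cutoff:
        return None
    covered_1 = set(alignment_a.values())
    covered_2 = set(alignment_b.values())
    preserved = sum(
        1 for i, j in template.interface.contacts if i in covered_1 and j in covered_2
    )
    return StructuralFeatureSet(
        tm_score=min(tm_a, tm_b),
        rmsd=max(sup_a.rmsd, sup_b.rmsd),
        preserved_interface_size=preserved,
        preserved_fraction=preserved / len(template.interface),
        template_id=template.template_id,
    )


def best_template_features(
    model_a: StructureChain,
    model_b: StructureChain,
    templates: list[tuple[ComplexTemplate, Alignment, Alignment]],
    *,
    tm_cutoff: float = TM_SCORE_CUTOFF,
) -> StructuralFeatureSet | None:
    """Best accepted template by (preserved_fraction, tm_score); None if none.

    Deterministic tie-break by template id.
    """
    best: StructuralFeatureSet | None = None
    for template, aln_a, aln_b in templates:
        features = build_interaction_model(
            model_a, model_b, template, aln_a, aln_b, tm_cutoff=tm_cutoff
        )
        if features is None:
            continue
        if best is None or (
            (features.preserved_fraction, features.tm_score, features.template_id or "")
            > (best.preserved_fraction, best.tm_score, best.template_id or "")
        ):
            best = features
    return best


def identity_alignment(length: int) -> Alignment:
    """Sequence-index identity mapping, the fixture default."""
    return {i: i for i in range(length)}
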