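"""Canonical protein-pair identifiers and gold-standard interaction sets.

Protein pairs are undirected: (A, B) and (B, A) denote the same physical
interaction.  Throughout the package a pair is stored as a tuple with the
two identifiers in lexicographic order after canonicalization (uppercase,
isoform suffix stripped), so that set membership and de-duplication are
well defined.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

_ISOFORM_SUFFIX = re.compile(r"\.\d+$")

Pair = tuple[str, str]


def canonical_id(identifier: str) -> str:
    """Normalize a gene/protein identifier.

    Uppercases and strips a trailing isoform suffix (``.1``, ``.2`` ...):
    the locus, not the splice form, is the node of the interactome.
    """
    ident = identifier.strip().upper()
    return _ISOFORM_SUFFIX.sub("", ident)


def canonical_pair(a: str, b: str, *, allow_self: bool = False) -> Pair:
    """Return the canonical (sorted) form of an undirected pair.

    Raises ``ValueError`` on a self-pair unless ``allow_self`` is set.
    """
    ca, cb = canonical_id(a), canonical_id(b)
    if ca == cb and not allow_self:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (ca, cb) if ca <= cb else (cb, ca)


@dataclass
class GoldStandardSet:
    """Experimentally supported positive interactions with per-pair source tags."""

    positives: set[Pair] = field(default_factory=set)
    sources: dict[Pair, set[str]] = field(default_factory=dict)
    snapshot_date: str | None = None

    def __len__(self) -> int:
        return len(self.positives)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.positives

    def add(self, a: str, b: str, source: str | None = None) -> Pair:
        pair = canonical_pair(a, b)
        self.positives.add(pair)
        if source is not None:
            self.sources.setdefault(pair, set()).add(source)
        return pair

    def proteins(self) -> set[str]:
        return {p for pair in self.positives for p in pair}

    def per_source_counts(self) -> dict[str, int]:
        """Unique-pair count per source tag (a pair may count for several)."""
        counts: dict[str, int] = {}
        for pair, tags in self.sources.items():
            for tag in tags:
                counts[tag] = counts.get(tag, 0) + 1
        return counts

    def pairwise_overlap(self, source_a: str, source_b: str) -> int:
        """Number of pairs tagged with both sources."""
        return sum(
            1
            for tags in self.sources.values()
            if source_a in tags and source_b in tags
        )


@dataclass
class PathwayCoreSet:
    """Named pathway (e.g. GA/IAA/CK/ET/ABA hormone signaling) and its core proteins."""

    name: str
    cores: set[str]

    def __post_init__(self) -> None:
        self.cores = {canonical_id(c) for c in self.cores}
        if not self.cores:
            raise ValueError(f"pathway {self.name!r} has no core proteins")
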