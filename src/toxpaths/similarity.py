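"""Compound lookup and fingerprint-based similar-substance retrieval.

Fingerprints are consumed as precomputed fixed-length bitstrings; similarity
is the Tanimoto (Jaccard) coefficient |a AND b| / |a OR b|, the field-standard
choice for binary molecular fingerprints.  The coefficient is a single
swappable function should another be preferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .knowledge_base import Compound, KnowledgeBase

__all__ = [
    "SimilarityHit",
    "CompoundNotFoundError",
    "AmbiguousCompoundError",
    "tanimoto",
    "find_compound",
    "top_k_similar",
]


class CompoundNotFoundError(LookupError):
    pass


class AmbiguousCompoundError(LookupError):
    def __init__(self, query: str, candidates: Sequence[str]):
        self.candidates = sorted(candidates)
        super().__init__(
            f"query {query!r} is ambiguous; candidates: {', '.join(self.candidates)}"
        )


@dataclass(frozen=True)
class SimilarityHit:
    query_compound_id: str
    hit_compound_id: str
    tanimoto: float


def _bits(fingerprint: str) -> np.ndarray:
    return np.frombuffer(fingerprint.encode("ascii"), dtype=np.uint8) - ord("0")


def tanimoto(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two equal-length bit
    vectors (bitstrings or 0/1 arrays).  Undefined when both are all-zero."""
    va = _bits(a) if isinstance(a, str) else np.asarray(a)
    vb = _bits(b) if isinstance(b, str) else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError(f"fingerprint length mismatch: {va.size} vs {vb.size}")
    union = int(np.count_nonzero(va | vb))
    if union == 0:
        raise ValueError("undefined similarity: both fingerprints are all-zero")
    return int(np.count_nonzero(va & vb)) / union


def find_compound(kb: KnowledgeBase, query: str) -> Compound:
    """Resolve a compound by exact match on id, name, CAS, EC or SMILES.

    Names are matched case-insensitively; ids, CAS, EC and SMILES
    case-sensitively.  A unique match is returned; otherwise
    :class:`CompoundNotFoundError` or :class:`AmbiguousCompoundError`.
    """
    query = query.strip()
    if not query:
        raise ValueError("empty query")
    query_ci = query.casefold()
    matches: list[Compound] = []
    for c in kb.compounds.values():
        if (
            query == c.compound_id
            or (c.cas and query == c.cas)
            or (c.ec and query == c.ec)
            or (c.smiles and query == c.smiles)
            or any(query_ci == name.casefold() for name in c.names)
        ):
            matches.append(c)
    if not matches:
        raise CompoundNotFoundError(f"compound not found: {query!r}")
    if len(matches) > 1:
        raise AmbiguousCompoundError(query, [c.compound_id for c in matches])
    return matches[0]


def top_k_similar(kb: KnowledgeBase, compound_id: str, k: int) -> list[SimilarityHit]:
    """The k most Tanimoto-similar fingerprinted compounds, descending, ties
    broken by compound_id; fewer than k returned when fewer exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    compound = kb.compounds.get(compound_id)
    if compound is None:
        raise ValueError(f"unknown compound {compound_id!r}")
    if not compound.fingerprint:
        raise ValueError(f"compound {compound_id!r} has no fingerprint")
    hits = [
        SimilarityHit(compound_id, other.compound_id, tanimoto(compound.fingerprint, other.fingerprint))
        for other in kb.compounds.values()
        if other.compound_id != compound_id and other.fingerprint
    ]
    hits.sort(key=lambda h: (-h.tanimoto, h.hit_compound_id))
    return hits[:k]
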