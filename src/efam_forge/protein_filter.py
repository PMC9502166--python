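"""Protein decontamination and dereplication.

Proteins with any strong (>95% identity) local hit to a prokaryotic
reference are removed unless every such hit carries a virus-related
keyword in its reference annotation.  Surviving proteins are
dereplicated at 100% sequence identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Annotation keywords that except a strong prokaryotic hit from removal.
VIRAL_KEYWORDS: tuple[str, ...] = (
    "tail",
    "capsid",
    "portal",
    "virus",
    "virion",
    "viral",
    "phage",
    "bacteriophage",
    "terminase",
)

DEFAULT_IDENTITY_CUTOFF = 95.0


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    contig_id: str = ""
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.rstrip("*").upper()
        if not seq:
            raise ValueError(f"protein {self.id!r} has empty sequence")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    qlen: int
    slen: int
    evalue: float
    bitscore: float
    subject_annotation: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} out of range")
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if self.aln_len < 1:
            raise ValueError("alignment length < 1")


@dataclass
class DereplicationMap:
    representative_of: dict[str, str] = field(default_factory=dict)

    @property
    def unique_count(self) -> int:
        return len(set(self.representative_of.values()))

    @property
    def duplicate_count(self) -> int:
        return len(self.representative_of) - self.unique_count

    def members_of(self, rep_id: str) -> list[str]:
        return [m for m, r in self.representative_of.items() if r == rep_id]


def _is_whitelisted(annotation: str | None, whitelist: Sequence[str]) -> bool:
    if not annotation:
        return False
    low = annotation.lower()
    return any(kw.lower() in low for kw in whitelist)


def flag_prokaryotic(
    hits: Iterable[HomologyHit],
    whitelist: Sequence[str] = VIRAL_KEYWORDS,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
) -> set[str]:
    """Return query ids to remove.

    A query is removed iff it has at least one hit with
    ``pident > identity_cutoff`` whose subject annotation does not
    contain any whitelist keyword (case-insensitive substring).  Every
    disqualifying hit must be individually excepted for the protein to
    survive; coverage is deliberately not considered.
    """
    removed: set[str] = set()
    for hit in hits:
        if hit.subject_annotation is None:
            raise ValueError(
                f"reference hit {hit.query_id}->{hit.subject_id} lacks a "
                "subject annotation column"
            )
        if hit.pident <= identity_cutoff:
            continue
        if _is_whitelisted(hit.subject_annotation, whitelist):
            continue
        removed.add(hit.query_id)
    return removed


def dereplicate(proteins: Sequence[ProteinRecord]) -> DereplicationMap:
    """Collapse 100%-identical sequences; first-seen id is representative."""
    rep_by_seq: dict[str, str] = {}
    mapping: dict[str, str] = {}
    for p in proteins:
        rep = rep_by_seq.setdefault(p.sequence, p.id)
        mapping[p.id] = rep
    return DereplicationMap(representative_of=mapping)


def filter_proteins(
    proteins: Sequence[ProteinRecord],
    ref_hits: Iterable[HomologyHit],
    whitelist: Sequence[str] = VIRAL_KEYWORDS,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
) -> tuple[list[ProteinRecord], set[str], DereplicationMap]:
    """Decontaminate then dereplicate.

    Returns (representative proteins, removed ids, dereplication map).
    """
    removed = flag_prokaryotic(ref_hits, whitelist, identity_cutoff)
    kept = [p for p in proteins if p.id not in removed]
    derep = dereplicate(kept)
    reps = {derep.representative_of[p.id] for p in kept}
    return [p for p in kept if p.id in reps], removed, derep
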