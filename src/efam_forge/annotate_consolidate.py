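"""Collapse per-protein database annotations to per-cluster summaries.

Descriptions from four source databases are grouped per cluster into
detailed (per-database) and consensus (multi-database agreement) views,
with informative/structural keyword classification and cluster-size
summary statistics.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sp_stats

from .family_graph import ClusterSet

logger = logging.getLogger(__name__)

SOURCE_DBS = ("kegg", "uniref90", "pfam", "vogdb")

UNINFORMATIVE_KEYWORDS = ("uncharacterized", "hypothetical", "no annotation")
_DUF_RE = re.compile(r"\bduf(\d+|\b)", re.IGNORECASE)

#: Structural keywords; a plain substring search is narrowed to
#: word-boundary matches for short/ambiguous tokens (toggleable).
STRUCTURAL_SUBSTRING = (
    "capsid",
    "virion",
    "fiber",
    "sheath",
    "structur",
    "spike",
    "baseplate",
)
STRUCTURAL_WORD = ("coat", "head", "neck", "mu", "tail", "gp23", "gp9")


@dataclass(frozen=True)
class AnnotationRecord:
    protein_id: str
    source_db: str
    accession: str
    description: str
    rank: str | None = None

    def __post_init__(self) -> None:
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source db {self.source_db!r}")


@dataclass
class ClusterAnnotation:
    cluster_id: str
    n_proteins: int
    detailed: list[tuple[str, str, int]] = field(default_factory=list)
    consensus: list[str] = field(default_factory=list)
    previously_annotated: bool = False
    structural: bool = False
    virion_associated: bool = False


def is_informative(description: str) -> bool:
    """False for empty descriptions and the unknown-function keyword set."""
    if not description or not description.strip():
        return False
    low = description.lower()
    if any(kw in low for kw in UNINFORMATIVE_KEYWORDS):
        return False
    if _DUF_RE.search(low):
        return False
    return True


def is_structural(description: str, word_boundaries: bool = True) -> bool:
    """Match against the structural keyword list (case-insensitive).

    `word_boundaries=False` reverts to the plain substring search for
    every keyword.
    """
    low = description.lower()
    if any(kw in low for kw in STRUCTURAL_SUBSTRING):
        return True
    if word_boundaries:
        return any(
            re.search(rf"\b{re.escape(kw)}\b", low) for kw in STRUCTURAL_WORD
        )
    return any(kw in low for kw in STRUCTURAL_WORD)


_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def normalize_description(description: str) -> str:
    return " ".join(description.lower().translate(_PUNCT_TABLE).split())


def collapse_cluster(
    cluster_id: str,
    members: Sequence[str],
    records: Iterable[AnnotationRecord],
    consensus_min_dbs: int = 2,
    word_boundaries: bool = True,
) -> ClusterAnnotation:
    """Collapse member annotations to detailed + consensus views."""
    member_set = set(members)
    per_db: dict[tuple[str, str], set[str]] = {}
    norm_dbs: dict[str, set[str]] = {}
    norm_example: dict[str, str] = {}
    informative: list[str] = []
    for rec in records:
        if rec.protein_id not in member_set:
            logger.warning(
                "annotation for %r not in cluster %s; skipped",
                rec.protein_id,
                cluster_id,
            )
            continue
        per_db.setdefault((rec.source_db, rec.description), set()).add(
            rec.protein_id
        )
        if is_informative(rec.description):
            informative.append(rec.description)
            norm = normalize_description(rec.description)
            norm_dbs.setdefault(norm, set()).add(rec.source_db)
            norm_example.setdefault(norm, norm)
    detailed = sorted(
        (db, desc, len(pids)) for (db, desc), pids in per_db.items()
    )
    consensus = sorted(
        norm for norm, dbs in norm_dbs.items() if len(dbs) >= consensus_min_dbs
    )
    return ClusterAnnotation(
        cluster_id=cluster_id,
        n_proteins=len(member_set),
        detailed=detailed,
        consensus=consensus,
        previously_annotated=bool(informative),
        structural=any(
            is_structural(d, word_boundaries) for d in informative
        ),
    )


def annotate_clusters(
    clusters: ClusterSet | Mapping[str, Sequence[str]],
    records: Iterable[AnnotationRecord],
    consensus_min_dbs: int = 2,
) -> list[ClusterAnnotation]:
    if isinstance(clusters, ClusterSet):
        cluster_map = {
            f"cluster_{i:06d}": members
            for i, members in enumerate(clusters.clusters)
        }
    else:
        cluster_map = dict(clusters)
    by_protein: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        by_protein.setdefault(rec.protein_id, []).append(rec)
    out = []
    for cid, members in cluster_map.items():
        recs = [r for m in members for r in by_protein.get(m, [])]
        out.append(
            collapse_cluster(cid, members, recs, consensus_min_dbs)
        )
    return out


def annotation_summary(
    annotations: Sequence[ClusterAnnotation],
    cluster_sizes: Mapping[str, int] | None = None,
) -> dict:
    """Annotated-fraction bookkeeping plus the annotated-vs-unannotated
    cluster-size comparison (two-sided Mann-Whitney U)."""
    if cluster_sizes is None:
        cluster_sizes = {a.cluster_id: a.n_proteins for a in annotations}
    n_total = len(annotations)
    annotated = [a for a in annotations if a.previously_annotated]
    unannotated = [a for a in annotations if not a.previously_annotated]
    per_db: dict[str, int] = {db: 0 for db in SOURCE_DBS}
    for a in annotations:
        dbs_informative = {
            db for db, desc, _ in a.detailed if is_informative(desc)
        }
        for db in dbs_informative:
            per_db[db] += 1
    sizes_ann = [cluster_sizes[a.cluster_id] for a in annotated]
    sizes_un = [cluster_sizes[a.cluster_id] for a in unannotated]
    summary: dict = {
        "n_clusters": n_total,
        "n_annotated": len(annotated),
        "annotated_pct": (
            round(100.0 * len(annotated) / n_total, 1) if n_total else None
        ),
        "per_db_annotated": per_db,
        "median_size_annotated": (
            float(np.median(sizes_ann)) if sizes_ann else None
        ),
        "median_size_unannotated": (
            float(np.median(sizes_un)) if sizes_un else None
        ),
    }
    if sizes_ann and sizes_un:
        u_stat, p_value = sp_stats.mannwhitneyu(
            sizes_ann, sizes_un, alternative="two-sided"
        )
        summary["mannwhitney_u"] = float(u_stat)
        summary["size_test_p"] = float(p_value)
    else:
        summary["size_test_p"] = None
        summary["size_test_note"] = "one group empty; test skipped"
    return summary
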