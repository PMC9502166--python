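"""Decoy-FDR thresholding of PSMs, peptide-to-protein mapping, and
virion-associated cluster annotation.

PSM tables are thresholded per independent search (per sample) at a
decoy-estimated FDR; surviving peptides map to proteins by exact
substring (I/L equivalent by default), fan out to duplicate members via
the dereplication map, and flag their clusters as virion-associated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotate_consolidate import ClusterAnnotation
from .protein_filter import DereplicationMap, ProteinRecord

logger = logging.getLogger(__name__)

MIN_PEPTIDE_LEN = 6
MAX_PEPTIDE_LEN = 50


def strip_flanking(peptide: str) -> str:
    """Strip `X.PEPTIDE.Y` flanking-residue notation."""
    parts = peptide.split(".")
    if len(parts) == 3:
        return parts[1]
    return peptide


@dataclass(frozen=True)
class PeptideSpectrumMatch:
    spectrum_id: str
    peptide: str
    score: float
    is_decoy: bool
    sample_id: str = "sample_1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", strip_flanking(self.peptide).upper())


@dataclass
class PeptideMatchResult:
    peptide: str
    matched_protein_ids: set[str] = field(default_factory=set)
    matched_cluster_ids: set[str] = field(default_factory=set)


def ingest_psms(
    psms: Iterable[PeptideSpectrumMatch],
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[PeptideSpectrumMatch]:
    """Drop out-of-length-range peptides, logging the count."""
    kept, dropped = [], 0
    for p in psms:
        if min_len <= len(p.peptide) <= max_len:
            kept.append(p)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d PSMs outside length range", dropped)
    return kept


def fdr_threshold(
    psms: Sequence[PeptideSpectrumMatch],
    target: float = 0.01,
    formula: str = "decoy_over_target",
) -> tuple[float | None, list[PeptideSpectrumMatch]]:
    """Score cutoff and surviving target PSMs for one search.

    FDR(s) = #decoys(score >= s) / max(1, #targets(score >= s)) by
    default (`formula="double_decoy"` uses 2D/(T+D)).  The cutoff is the
    smallest score whose FDR is within `target` while maximizing the
    surviving target set; decoys never survive.
    """
    if not psms:
        return None, []
    ranked = sorted(psms, key=lambda p: -p.score)
    n_targets = n_decoys = 0
    best_cutoff: float | None = None
    best_targets = -1
    for i, p in enumerate(ranked):
        if p.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        if i + 1 < len(ranked) and ranked[i + 1].score == p.score:
            continue  # only evaluate at distinct score boundaries
        if formula == "double_decoy":
            fdr = 2 * n_decoys / max(1, n_targets + n_decoys)
        else:
            fdr = n_decoys / max(1, n_targets)
        if fdr <= target and n_targets > best_targets:
            best_targets = n_targets
            best_cutoff = p.score
    if best_cutoff is None:
        return None, []
    survivors = [
        p for p in ranked if not p.is_decoy and p.score >= best_cutoff
    ]
    return best_cutoff, survivors


def fdr_threshold_by_sample(
    psms: Sequence[PeptideSpectrumMatch],
    target: float = 0.01,
    formula: str = "decoy_over_target",
) -> dict[str, tuple[float | None, list[PeptideSpectrumMatch]]]:
    """Apply the FDR cutoff independently per sample_id."""
    by_sample: dict[str, list[PeptideSpectrumMatch]] = {}
    for p in psms:
        by_sample.setdefault(p.sample_id, []).append(p)
    return {
        sid: fdr_threshold(rows, target, formula)
        for sid, rows in sorted(by_sample.items())
    }


def _il_normalize(seq: str) -> str:
    return seq.replace("I", "L")


def map_peptides(
    peptides: Iterable[str],
    proteins: Sequence[ProteinRecord],
    cluster_of: Mapping[str, Sequence[str]] | None = None,
    derep: DereplicationMap | None = None,
    il_equivalent: bool = True,
) -> list[PeptideMatchResult]:
    """Exact-substring peptide-to-protein mapping.

    `cluster_of` maps protein id -> cluster ids.  When a dereplication
    map is given, a hit on a representative fans out to all duplicate
    members.
    """
    cluster_of = cluster_of or {}
    fanout: dict[str, list[str]] = {}
    if derep is not None:
        for member, rep in derep.representative_of.items():
            fanout.setdefault(rep, []).append(member)
    prepared = [
        (p.id, _il_normalize(p.sequence) if il_equivalent else p.sequence)
        for p in proteins
    ]
    results = []
    for pep in sorted(set(peptides)):
        needle = _il_normalize(pep) if il_equivalent else pep
        matched: set[str] = set()
        for pid, seq in prepared:
            if needle in seq:
                matched.add(pid)
                matched.update(fanout.get(pid, ()))
        clusters = {
            cid for pid in matched for cid in cluster_of.get(pid, ())
        }
        results.append(
            PeptideMatchResult(
                peptide=pep,
                matched_protein_ids=matched,
                matched_cluster_ids=clusters,
            )
        )
    return results


def annotate_virion(
    matches: Sequence[PeptideMatchResult],
    cluster_annotations: Sequence[ClusterAnnotation],
) -> tuple[list[ClusterAnnotation], dict]:
    """Flag peptide-matched clusters as virion-associated and report the
    de-novo / concordance statistics."""
    by_id = {a.cluster_id: a for a in cluster_annotations}
    matched_ids: set[str] = set()
    for m in matches:
        for cid in m.matched_cluster_ids:
            if cid not in by_id:
                logger.warning("peptide match to unknown cluster %r", cid)
                continue
            matched_ids.add(cid)
    for cid in matched_ids:
        by_id[cid].virion_associated = True
    n_total = len(cluster_annotations)
    n_matched = len(matched_ids)
    matched = [by_id[cid] for cid in matched_ids]
    de_novo = [a for a in matched if not a.previously_annotated]
    prior = [a for a in matched if a.previously_annotated]
    non_structural_prior = [a for a in prior if not a.structural]
    stats = {
        "n_clusters": n_total,
        "n_matched": n_matched,
        "matched_pct": (
            round(100.0 * n_matched / n_total, 1) if n_total else None
        ),
        "n_de_novo": len(de_novo),
        "de_novo_pct": (
            round(100.0 * len(de_novo) / n_matched, 1) if n_matched else None
        ),
        "n_prior_annotated": len(prior),
        "n_prior_non_structural": len(non_structural_prior),
        "discordant_pct": (
            round(100.0 * len(non_structural_prior) / len(prior), 1)
            if prior
            else None
        ),
    }
    return list(cluster_annotations), stats
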